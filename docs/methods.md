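# Methods

This note documents the models, the synthetic-data design, the
numerical choices and the known limitations of `adentropy`. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## The synthetic plant generator

Industrial AD operating records are not public, so the package's
reference data come from a generator (`adentropy.synth`) built to
reproduce the statistical structure of a six-month, ~10,000-record
campaign from a ~30 t/d digestion line.

**Inputs.** The six measured inputs (feed solids %, organic matter %,
feed rate t/h, pH, dissolved O₂ mg/L, total solids %) are drawn from a
Gaussian copula: latent standard normals with a target correlation
matrix, transformed through truncated-normal marginals whose parent
parameters are solved (2-D root find on the truncated moments) so the
*realized* mean/SD equal the configured values exactly. Truncation
bounds are wide physical limits, not the narrow operating bands — a
variable reported as 34.2 ± 2.5 °C cannot live inside a 30–35 °C band;
those bands act as state-classification and cleaning thresholds
instead. Dissolved oxygen is a near-inert seal-integrity indicator and
participates only weakly (target r = −0.05 with yield).

**Outputs.** Biogas yield (m³/t), reactor temperature (°C) and VFA
(g/L) come from a deterministic response kernel plus Gaussian noise.
The kernel is an affine combination of the standardized inputs plus two
non-linear terms:

* a saturating interaction `tanh(u_solids)·u_organic` — the
  organic-matter effect is modulated by solids level and saturates at
  extreme loads (mass-transfer limitation / hydraulic dilution);
* an overload-inhibition response
  `logistic(6·(u_solids − 1.2)) · (1 + 0.4·u_rate)` — a sharp threshold
  in solids, amplified by feed rate. Inhibition onset in a digester is
  a threshold phenomenon (hydrolysis outpacing methanogenesis), and the
  steep transition is what gives the plant the fine-scale structure on
  which model families genuinely differ. It enters the gas yield with a
  negative coefficient and VFA with a positive one.

Both bases are residualized against the linear span of the inputs on an
internal 30,000-row calibration sample, so their variance shares are
purely non-linear and do not disturb the Pearson targets. The linear
coefficients are then solved by moment matching (empirical covariances
on the calibration sample) so the realized correlations hit the
configured targets; the residual noise variance closes the marginal SD
budget exactly. A configuration whose targets leave no noise budget (or
no positive semi-definite completion) is rejected at construction. A
guard keeps gas yield monotone increasing in organic matter, shrinking
the interaction coefficient if necessary.

**Default correlation targets.** The three printed feed-solids pairs
(0.90 with yield, 0.85 with temperature, 0.60 with VFA) are fixed; the
remaining defaults (organic matter 0.70 / feed rate 0.45 / pH 0.10 /
DO −0.05 with yield; input–input structure with total solids kept below
the 0.40 core-screening threshold) preserve the core ≫ auxiliary
dominance ordering and are all overridable.

**Time structure.** Records are emitted at the 5-minute SCADA cadence
from a fixed origin (2024-03-01). Regimes (steady / load fluctuation /
seasonal, mix 0.60/0.25/0.15) occupy contiguous 12–48 h segments. Load
fluctuation adds block-wise step changes (4–12 h blocks) to a common
feed-quality factor loading on solids and feed rate, variance-
preserving; the seasonal regime adds a slow sinusoid (period = dataset
span, amplitude 1.2 °C) to temperature. Regime mean shifts (load
fluctuation: −2.0 m³/t, +1.1 g/L VFA, +0.3 °C) reproduce the
steady-vs-load exemplar pattern.

**Exact-mean sampling.** Latent draws, block factors, the seasonal
wave, output noise and regime shifts are centred per realization
(regime shifts against the realized regime proportions). This removes
Monte-Carlo drift of campaign-wide sample means without touching
variances or correlations; it is part of the generator's contract that
a default campaign reproduces the configured statistics to within
ordinary sampling error. `true_response` uses the configured-mix
centring as its fixed reference frame, so generated outputs equal the
kernel plus noise up to a per-realization constant of order n^(−1/2).

**Faults.** `round(n · fault_rate)` records (default 2.3 %) are
overwritten to violate exactly one cleaning limit each (temperature
> 80 °C, feed solids > 40 %, organic matter > 50 %, or negative yield),
uniformly among the four modes, and flagged. Cleaning by
`remove_outliers` recovers exactly this set on default data.

**What the generator does not emulate.** No mechanistic digestion
kinetics (no ADM1), no microbial state, no sensor drift or
autocorrelated measurement noise, no per-variable missingness, no
severe acidification or oxygen-ingress events. Tests passing on this
generator show that the *pipeline and estimators* behave correctly
under the documented statistical structure — not that any model family
would rank the same way on a particular real plant.

## Preprocessing protocol

Cleaning limits default to the fault thresholds above. Min–max
parameters are fitted on the training block only and applied without
clipping (values outside the training range leave [0, 1]); the fitted
parameters are frozen, which the suite asserts as an
information-leakage guard. The 7:2:1 split is chronological by default
— the deployment story is temporal — with a seeded random mode
retained. The Kolmogorov–Smirnov check is per variable with asymptotic
p-values; a split "passes" when all monitored variables give p > 0.05.
Feature screening keeps inputs with |r| ≥ 0.40 against the target as
core; 0.40 separates the strong printed pairs (≥ 0.45) from the weak
auxiliaries under the default structure, and prediction outputs never
compete as candidate predictors. Records with missing fields are
dropped, never imputed.

## Models

SVM and random-forest internals delegate to scikit-learn (`SVC`/`SVR`,
`RandomForest*` with `max_features = mtry`); they are standard
components, not this package's contribution. Classification targets
the engineering threshold: yield ≥ 70 m³/t is high (+1). The SVM
decision-function value serves as the AUROC score (the forest uses its
mean class vote); ε for support-vector regression defaults to 0.1 in
scaled units.

The neural network is implemented here in NumPy so the training
objective is exactly the documented penalized least squares
`L = (1/N)Σ‖ŷᵢ−yᵢ‖² + λ‖θ‖²` (θ = all weights and biases), with Adam
(β₁ = 0.9, β₂ = 0.999), mini-batches of 64, early stopping on
validation MSE with patience 20 over at most 500 epochs, and
best-weight restoration. Fits are deterministic given the seed. The
default penalty is λ = 1e-4: the objective acts on min–max-scaled
multi-target errors whose squared magnitudes are O(10⁻³), and at
λ = 10⁻³ the penalty term dominates the data term roughly 100:1 at
initialization, collapsing the network to a near-linear map; 10⁻⁴
restores the intended mild regularization on this loss scale. λ remains
a searchable hyperparameter (grid 0–0.01). The compact
two-layer 32-unit architecture is available as `ANN_COMPACT`.

A note on exactness: a constant target is recovered exactly by SVM/RF,
but a stochastic first-order optimizer settles only within its
step-size scale (~10⁻³–10⁻²); the suite asserts the ANN's constant-fit
accuracy at that realistic tolerance.

## Entropy estimators

All entropies are natural-log (nats).

**Error entropy.** Gaussian KDE with the robust Silverman bandwidth
`0.9·min(s, IQR/1.34)·n^(−1/5)`. Two evaluations of `−∫ p ln p` are
provided: the default is the leave-one-out plug-in sum
`−(1/n) Σᵢ ln p̂₋ᵢ(eᵢ)`, which has small bias for both smooth and
compactly supported error laws (measured at n = 10,000: −0.001 nats for
N(0,1), +0.039 for U(0,1)); trapezoid quadrature on a uniform grid
(2048 points, padded 4 bandwidths, density renormalized to unit mass)
is retained as an option and its grid mass is always reported as a
diagnostic. Quadrature carries a ≈ +0.07-nat boundary-smoothing bias
for uniform errors, which is why it is not the default. Degenerate
(constant) samples are refused rather than returned as −∞; the minimum
sample size is 10.

**Entropy increase.** ΔH_j averages H(e^(j)) − H(e) over 10 seeded
permutations of column j by default (a single permutation is noisy;
the per-permutation values are reported so the averaging is
transparent).

**Process entropy.** Empirical state probabilities with 0·ln 0 ≡ 0,
bounded by [0, ln 4]. The four states are classified by thresholds the
operating bands imply — VFA > 8 g/L, temperature outside 30–35 °C,
overload as feed rate > 2.0 t/h or yield < 70 m³/t — with a fixed
priority order (VFA accumulation ≻ overload ≻ temperature deviation)
for multi-violation records. These thresholds are the module's largest
inferred element and are fully configurable; the default observation
window for per-window state distributions is 24 h.

## Operation campaign simulation

The 12-week comparison simulates the plant at 5-minute cadence with
three disturbance components: persistent feed-quality shocks (Poisson
arrivals at 0.125 h⁻¹ of piecewise-constant levels, SD 3.8 latent
units, loading on solids/organic/rate at 1.0/0.7/0.5), white yield
noise (10.5 m³/t per 5-min sample), and a slow seasonal drift
(2.0 m³/t). The shock magnitude and noise floor are *calibrations*,
set so baseline operation shows an hourly-yield CV of about 18 % and
the unpredictable floor alone about 4–5 % — the campaign's documented
before/after operating envelope — and they are declared as such, not
discovered.

Assisted operation is advisory, never an actuator loop: the intake
measurement makes the incoming feed observable one hour ahead, which
covers the hourly operator decision cycle, so the operator can schedule
feed blending and rate trimming for the coming hour. The counter-action
is computed by inverting the advisory model's predicted-deviation curve
(the operator titrates the feed toward the model's predicted-nominal
point); its feed-rate component is clipped to the pump range
0.5–2.0 t/h. A zero-gain policy reproduces the baseline series
bit-for-bit under the same seed, and a perfect-prediction oracle
removes the predictable component entirely, leaving the unpredictable
floor. Stability statistics: CV of hourly yield, daily CV indices
(CV of each day's 24 hourly yields) compared by Welch's t-test, process
entropy of the hourly state sequence, and an organic-degradation proxy
(nominal 84 %, reduced by VFA excess beyond 8 g/L and thermal
excursions) asserted not to degrade under assistance.

The relative stability improvement is reported by the definition
(CV_b − CV_a)/CV_b; for the 18 % → 5 % pair this is 0.72, and that is
the number the code produces.

## Techno-economics and emissions

Deterministic arithmetic: power-law capacity scaling with α = 0.65 from
a 30 t/d reference; discounted payback (8 %, 10 years) with linear
interpolation inside the crossing year and `None` when break-even is
not reached within the lifetime; annual savings at 330 uptime days;
avoided CO₂ = intensity × throughput × savings rate × grid factor for
the three regional grid factors (0.65 / 0.35 / 0.45 kg CO₂ per kWh,
reading the factor in standard kg-per-kWh units). Capital cost is a
required user input — no public capex exists for the studied retrofit,
so absolute payback is scenario output, not a reproduced value; a
tabular sensitivity sweep (operating saving × discount rate) stands in
for a payback-surface figure.

## Pipeline and reproducibility

`run_pipeline` executes generate → preprocess → train → evaluate →
entropy → operate → tea → report, each stage writing CSV/JSON artifacts
and a manifest (stage seed, package version, SHA-256 of inputs and
outputs). One global seed fans out to stage seeds by fixed offsets
(+0 generation, +100 training, +200 entropy, +300 operation), so stages
are independently re-runnable; rerunning a deterministic stage
reproduces identical hashes. The reporter only assembles stage
artifacts and recomputes nothing.

Problem sizes used throughout the package's own checks: 10,000-record
campaigns (the study scale), 30,000-row generator calibration samples,
12-week (2016-hour) operation scenarios, and 10-seed replications for
distributional claims.

## Known limitations

* The generator's dependence structure is a Gaussian copula; real plant
  data show autocorrelation, sensor drift and heavier tails than any of
  its components.
* Error entropy is computed from deterministic residuals; predictive
  (Bayesian/ensemble) entropy is out of scope.
* The advisory simulation abstracts feed management into a latent
  counter-shock; it contains no PID/actuator dynamics and no closed-
  loop optimization.
* Model-family comparisons (RMSE order, entropy order) are properties
  of the generator's documented response structure; they are evidence
  about the estimators, not about any particular real digester.
* The forest cannot beat a linear baseline on the *noise-free* kernel:
  with a 0.90 linear variance share, the non-linear signal is small
  enough that the forest's piecewise-constant approximation error
  exceeds the linear model's interaction residual. The suite therefore
  asserts the network's superiority and the kernel's non-linearity, not
  a forest-vs-linear ordering.
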