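# adentropy

Entropy-guided machine learning for industrial anaerobic-digestion (AD)
operation: soft-sensor prediction of biogas yield, reactor temperature
and volatile fatty acid (VFA) concentration, information-theoretic
uncertainty quantification, and a simulated advisory loop that turns
one-hour-ahead forecasts into operational stability.

## Who this is for

Process engineers and researchers working on data-driven monitoring of
full-scale digesters. Industrial AD datasets are rarely public, so the
package ships a first-class synthetic plant-record generator that
reproduces the statistical structure of a six-month, ~10,000-record
industrial campaign (marginal moments, the dominant feed-solids
correlations r = 0.90 / 0.85 / 0.60 with the three performance outputs,
three operating regimes at 5-minute cadence, and ~2.3 % sensor-fault
records). Every downstream method is testable against that generator's
known ground truth.

## The methods at the core

Three soft-sensor families are trained under one protocol (cleaning by
engineering limits, min–max scaling `x' = (x − x_min)/(x_max − x_min)`
fitted on the training block only, chronological 7:2:1 split with a
two-sample Kolmogorov–Smirnov homogeneity check, Pearson-correlation
feature screening): an RBF-kernel SVM (C = 10, γ = 0.05), a random
forest (B = 100, depth 18, mtry = 2), and a multi-output feed-forward
network ([128, 64], ReLU, Adam) minimising

```
L = (1/N) Σᵢ ‖ŷᵢ − yᵢ‖² + λ‖θ‖²
```

with early stopping on validation loss. Beyond RMSE/R², accuracy, F1
and AUROC, uncertainty is quantified with three entropy measures (all
in nats):

* **Error entropy** `H(e) = −∫ p(ξ) ln p(ξ) dξ` of the residuals
  `e = y − ŷ`, estimated by Gaussian-kernel density estimation with the
  robust Silverman bandwidth `h = 0.9·min(s, IQR/1.34)·n^(−1/5)`.
* **Entropy increase** `ΔH_j = H(e^(j)) − H(e)` after permuting feature
  j — an information-theoretic feature-contribution index that mirrors
  forest importance and permutation ΔRMSE.
* **Process entropy** `S_proc = −Σ_k π_k ln π_k` over four discrete
  operating states (normal, VFA accumulation, overload, temperature
  deviation), the macroscopic order parameter of plant operation.

A 12-week campaign simulator compares baseline operation against
advisory-assisted operation (the fitted model forecasts the effect of
incoming feed one hour ahead; the operator counteracts by feed blending
and rate trimming within 0.5–2.0 t/h). Stability is scored by the
coefficient of variation (CV = sd/mean) of hourly gas yield, Welch's
t-test on daily CV indices, and process entropy. Techno-economic and
emission arithmetic (capacity scaling `cost ∝ capacity^0.65`,
discounted payback at 8 % over 10 years, regional grid emission
factors) completes the assessment.

## Worked example

```python
import adentropy as ad

# synthetic plant campaign with the study's statistical structure
gen = ad.PlantDataGenerator()
table = gen.generate(10_000, seed=1)
ok = table[~table.fault_flag]
print(round(ok.feed_solids.corr(ok.biogas_yield), 3))   # 0.898
print(round(ok.biogas_yield.mean(), 1))                 # 79.5

# shared protocol: clean, split, scale, train the network
clean, removed = ad.remove_outliers(table)              # removed == 230
train, val, test = ad.split(clean)
params = ad.minmax_fit(train)
feats = list(ad.synth.INPUT_VARIABLES)
targs = list(ad.synth.OUTPUT_VARIABLES)
trs, vas, tes = (ad.minmax_apply(t, params) for t in (train, val, test))
ann = ad.fit_model(ad.ANNSpec(), trs[feats], trs[targs],
                   validation=(vas[feats], vas[targs]), normalization=params)

# residual uncertainty on held-out data
H = ad.model_error_entropy(ann, tes[feats], tes[targs], target="biogas_yield")
print(round(H.H, 2))                                    # -1.8 nats

# baseline vs assisted 12-week campaign
base = ad.simulate_operation(None, weeks=12, seed=42)
asst = ad.simulate_operation(ad.AdvisoryPolicy(model=ann), weeks=12, seed=42)
print(round(100 * base.cv, 1), round(100 * asst.cv, 1)) # 17.9  4.6
print(round(base.s_proc, 2), round(asst.s_proc, 2))     # 1.31  0.42
```

The campaign numbers say: unassisted, hourly gas yield fluctuates with
an ~18 % coefficient of variation and the plant wanders through
abnormal states (process entropy 1.31 nats); with the advisory loop the
fluctuation drops below 5 % and operation concentrates in the normal
state (0.42 nats). Negative error entropy simply reflects a residual
distribution much narrower than one unit of scaled yield.

The same workflow is scriptable end to end:

```bash
adentropy run --outdir run_default          # all stages, packaged config
adentropy generate preprocess --outdir run  # individual stages
```

Each stage writes CSV/JSON artifacts plus a manifest with seeds and
content hashes, so reruns are verifiably reproducible.

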