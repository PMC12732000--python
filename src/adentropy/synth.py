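"""Synthetic plant-record generator for an industrial anaerobic digester.

The generator emulates the statistical structure of six months of
5-minute SCADA / laboratory records from a full-scale digestion line:

* nine process variables with prescribed marginal means, standard
  deviations and physical ranges,
* a prescribed Pearson correlation structure (feed solids dominate the
  three performance outputs),
* three operating regimes (steady, load fluctuation, seasonal),
* a small fraction of sensor-fault records that violate cleaning limits.

Inputs are drawn from a Gaussian copula with truncated-normal marginals.
The three performance outputs (biogas yield, reactor temperature, VFA)
are produced by a deterministic response kernel -- an affine combination
of the standardized inputs plus a multiplicative solids x organic-matter
interaction and regime shifts -- with additive Gaussian noise.  The
kernel coefficients are calibrated once per configuration by moment
matching on an internal sample, so that the realized correlations and
marginal moments hit their targets simultaneously.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr
from scipy.stats import truncnorm

from .exceptions import ConfigurationError

__all__ = [
    "INPUT_VARIABLES",
    "OUTPUT_VARIABLES",
    "PROCESS_VARIABLES",
    "REGIMES",
    "Marginal",
    "GeneratorConfig",
    "PlantDataGenerator",
    "default_config",
    "generate_records",
    "true_response",
    "inject_faults",
    "write_records",
    "read_records",
]

INPUT_VARIABLES = (
    "feed_solids",
    "organic_matter",
    "feed_rate",
    "ph",
    "dissolved_o2",
    "total_solids",
)
OUTPUT_VARIABLES = ("biogas_yield", "temperature", "vfa")
PROCESS_VARIABLES = INPUT_VARIABLES + OUTPUT_VARIABLES
REGIMES = ("steady", "load_fluctuation", "seasonal")
CORE_VARIABLES = ("feed_solids", "organic_matter", "feed_rate")

#: fixed origin of the synthetic campaign (plant start of records)
START_TIMESTAMP = pd.Timestamp("2024-03-01 00:00:00")
#: SCADA logging cadence
SAMPLING_MINUTES = 5

_CALIBRATION_SEED = 20240301  # internal; independent of the user seed
_CALIBRATION_SIZE = 30_000


@dataclass(frozen=True)
class Marginal:
    """Marginal description of one process variable.

    ``mean``/``sd`` are the moments of the *realized* (truncated)
    distribution; ``lower``/``upper`` are hard physical bounds used for
    truncation (``None`` means unbounded on that side).
    """

    mean: float
    sd: float
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ConfigurationError(f"marginal sd must be > 0, got {self.sd}")
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        if not lo < hi:
            raise ConfigurationError(f"marginal bounds must satisfy lower < upper ({lo} >= {hi})")


# Table-of-record operating statistics of the studied plant: mean +/- SD per
# variable, with wide physical truncation bounds.  The narrow "engineering
# threshold" bands (e.g. temperature 30-35 degC) are *state-classification*
# bands, not hard limits: a variable with mean 34.2 and SD 2.5 cannot live
# inside a 5-degree band, so truncation uses physical/cleaning bounds instead.
_DEFAULT_MARGINALS: tuple[tuple[str, Marginal], ...] = (
    ("feed_solids", Marginal(26.5, 4.2, 15.0, 40.0)),
    ("organic_matter", Marginal(28.7, 5.1, 12.0, 50.0)),
    ("feed_rate", Marginal(1.2, 0.3, 0.3, 2.1)),
    ("ph", Marginal(7.2, 0.4, 6.0, 8.4)),
    ("dissolved_o2", Marginal(0.25, 0.10, 0.0, 0.6)),
    ("total_solids", Marginal(32.4, 3.5, 20.0, 45.0)),
    ("biogas_yield", Marginal(79.5, 6.1, 0.0, None)),
    ("temperature", Marginal(34.2, 2.5, None, None)),
    ("vfa", Marginal(6.3, 1.5, 0.0, None)),
)

# Pearson correlation targets.  The strong trio (feed solids vs the three
# outputs: 0.90 / 0.85 / 0.60) is the plant's printed structure; the
# remaining entries keep the dominance ordering core >> auxiliary and are
# fully overridable.
_DEFAULT_CORR_TARGETS: tuple[tuple[str, str, float], ...] = (
    # input-input structure
    ("feed_solids", "organic_matter", 0.55),
    ("feed_solids", "feed_rate", 0.30),
    ("organic_matter", "feed_rate", 0.25),
    ("feed_solids", "total_solids", 0.40),
    ("organic_matter", "total_solids", 0.20),
    ("feed_solids", "ph", 0.10),
    # input-output structure
    ("feed_solids", "biogas_yield", 0.90),
    ("feed_solids", "temperature", 0.85),
    ("feed_solids", "vfa", 0.60),
    ("organic_matter", "biogas_yield", 0.70),
    ("feed_rate", "biogas_yield", 0.45),
    ("ph", "biogas_yield", 0.10),
    ("dissolved_o2", "biogas_yield", -0.05),
    ("organic_matter", "temperature", 0.50),
    ("feed_rate", "temperature", 0.30),
    ("organic_matter", "vfa", 0.45),
    ("feed_rate", "vfa", 0.35),
)

_DEFAULT_REGIME_MIX: tuple[tuple[str, float], ...] = (
    ("steady", 0.60),
    ("load_fluctuation", 0.25),
    ("seasonal", 0.15),
)

# Raw per-regime mean shifts of the outputs (output units).  They are
# re-centred under the regime mix at calibration time so the campaign-wide
# means stay on target; only the *differences* between regimes matter.
# Load fluctuation depresses yield and accumulates VFA relative to steady
# operation, as in the plant's exemplar records.
_DEFAULT_REGIME_EFFECTS: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = (
    ("steady", (("biogas_yield", 0.0), ("temperature", 0.0), ("vfa", 0.0))),
    ("load_fluctuation", (("biogas_yield", -2.0), ("temperature", 0.3), ("vfa", 1.1))),
    ("seasonal", (("biogas_yield", -0.5), ("temperature", 0.0), ("vfa", -0.3))),
)

#: share of output variance carried by the solids x organic interaction
#: (signed: the sign of the value is the sign of the coefficient)
_DEFAULT_INTERACTION_SHARE: tuple[tuple[str, float], ...] = (
    ("biogas_yield", 0.01),
    ("temperature", 0.03),
    ("vfa", 0.04),
)

#: share of output variance carried by the overload-inhibition response
#: (signed; negative for gas yield: overload suppresses methanogenesis)
_DEFAULT_OVERLOAD_SHARE: tuple[tuple[str, float], ...] = (
    ("biogas_yield", -0.045),
    ("temperature", 0.01),
    ("vfa", 0.08),
)


def _interaction_basis(u_solids: np.ndarray, u_organic: np.ndarray) -> np.ndarray:
    """Saturating multiplicative interaction of the two composition drivers.

    ``tanh(u_solids) * u_organic``: the organic-matter effect is amplified
    or damped by the solids level, saturating at extreme solids loads
    (scum formation / mass-transfer limitation on the high side,
    hydraulic dilution on the low side).
    """
    return np.tanh(u_solids) * u_organic


def _overload_basis(u_solids: np.ndarray, u_rate: np.ndarray) -> np.ndarray:
    """Organic-loading overload response: a sharp threshold in feed solids,
    amplified by feed rate.

    Once solids push the organic loading rate past the plant's comfortable
    envelope (about +1.2 SD), hydrolysis outpaces methanogenesis: gas
    yield drops and VFA accumulates.  The transition is steep -- a
    logistic in solids with scale 1/6 SD -- because inhibition onset in a
    digester is a threshold phenomenon, not a gradual slope.
    """
    return 1.0 / (1.0 + np.exp(-6.0 * (u_solids - 1.2))) * (1.0 + 0.4 * u_rate)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic-plant generator.

    The configuration is hashable (all collection fields are tuples) so
    calibration results can be cached per configuration.
    """

    marginals: tuple[tuple[str, Marginal], ...] = _DEFAULT_MARGINALS
    corr_targets: tuple[tuple[str, str, float], ...] = _DEFAULT_CORR_TARGETS
    regime_mix: tuple[tuple[str, float], ...] = _DEFAULT_REGIME_MIX
    regime_effects: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = _DEFAULT_REGIME_EFFECTS
    interaction_share: tuple[tuple[str, float], ...] = _DEFAULT_INTERACTION_SHARE
    overload_share: tuple[tuple[str, float], ...] = _DEFAULT_OVERLOAD_SHARE
    #: optional per-output residual-noise override (output units); ``None``
    #: entries are derived so the marginal SD closes exactly.
    noise_sd: tuple[tuple[str, float | None], ...] = (
        ("biogas_yield", None),
        ("temperature", None),
        ("vfa", None),
    )
    fault_rate: float = 0.023
    seed: int = 1
    #: seasonal-regime sinusoidal temperature modulation, degC amplitude
    seasonal_temp_amplitude: float = 1.2
    #: regime segment durations, hours (uniform)
    segment_hours: tuple[int, int] = (12, 48)
    #: load-fluctuation step-change block durations, hours (uniform)
    load_block_hours: tuple[int, int] = (4, 12)
    #: variance share of the common load factor within load blocks
    load_factor_share: float = 0.3
    #: loadings of the load factor on (feed_solids, feed_rate)
    load_factor_loadings: tuple[float, float] = (1.0, 0.8)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.marginals]
        if list(dict.fromkeys(names)) != names:
            raise ConfigurationError("duplicate marginal entries")
        missing = set(PROCESS_VARIABLES) - set(names)
        if missing:
            raise ConfigurationError(f"marginals missing for {sorted(missing)}")
        mix = dict(self.regime_mix)
        if set(mix) != set(REGIMES):
            raise ConfigurationError(f"regime_mix must cover {REGIMES}")
        if any(p < 0 for p in mix.values()) or abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("regime_mix proportions must be >= 0 and sum to 1")
        if not 0.0 <= self.fault_rate <= 0.1:
            raise ConfigurationError("fault_rate must lie in [0, 0.1]")
        for a, b, r in self.corr_targets:
            if a not in PROCESS_VARIABLES or b not in PROCESS_VARIABLES:
                raise ConfigurationError(f"unknown variable in corr_targets: ({a}, {b})")
            if not -1.0 < r < 1.0:
                raise ConfigurationError(f"correlation target out of (-1, 1): ({a}, {b}, {r})")
        # positive semi-definiteness of the implied latent correlation blocks
        R = self.input_correlation()
        if np.linalg.eigvalsh(R).min() < -1e-9:
            raise ConfigurationError("input correlation targets are not positive semi-definite")
        # feasibility of each output's constrained correlations: with the
        # unconstrained entries free, a PSD completion exists iff the
        # systematic variance share r' R^-1 r on the constrained support
        # does not exceed 1.
        targets = self.output_targets()
        idx = {v: i for i, v in enumerate(INPUT_VARIABLES)}
        for out in OUTPUT_VARIABLES:
            S = [idx[v] for v in INPUT_VARIABLES if (v, out) in targets]
            if not S:
                continue
            r = np.array([targets[(v, out)] for v in INPUT_VARIABLES if (v, out) in targets])
            share = float(r @ np.linalg.solve(R[np.ix_(S, S)], r))
            if share > 1.0 - 1e-9:
                raise ConfigurationError(
                    f"correlation targets for {out!r} have no positive semi-definite "
                    f"completion (systematic share {share:.3f} > 1)"
                )

    # -- convenience accessors -------------------------------------------------

    def marginal(self, name: str) -> Marginal:
        return dict(self.marginals)[name]

    def mix(self) -> dict[str, float]:
        return dict(self.regime_mix)

    def input_correlation(self) -> np.ndarray:
        """Latent 6x6 correlation matrix of the input copula."""
        idx = {v: i for i, v in enumerate(INPUT_VARIABLES)}
        R = np.eye(len(INPUT_VARIABLES))
        for a, b, r in self.corr_targets:
            if a in idx and b in idx:
                R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
        return R

    def output_targets(self) -> dict[tuple[str, str], float]:
        """Map (input, output) -> target Pearson correlation."""
        out: dict[tuple[str, str], float] = {}
        for a, b, r in self.corr_targets:
            if a in INPUT_VARIABLES and b in OUTPUT_VARIABLES:
                out[(a, b)] = r
            elif b in INPUT_VARIABLES and a in OUTPUT_VARIABLES:
                out[(b, a)] = r
        return out


def default_config(**overrides) -> GeneratorConfig:
    """The packaged default configuration (plant statistics + correlations)."""
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


def _solve_truncnorm_params(m: Marginal) -> tuple[float, float, float, float]:
    """Parent ``(mu, sigma)`` and standardized bounds ``(a, b)`` of a
    truncated normal whose *truncated* moments equal ``(mean, sd)``."""
    lo = -np.inf if m.lower is None else m.lower
    hi = np.inf if m.upper is None else m.upper
    if not np.isfinite(lo) and not np.isfinite(hi):
        return m.mean, m.sd, -np.inf, np.inf

    def residual(p):
        mu, log_sigma = p
        sigma = float(np.exp(log_sigma))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        mean, var = truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(mean) - m.mean, float(np.sqrt(var)) - m.sd]

    sol = optimize.root(residual, x0=[m.mean, np.log(m.sd)], method="hybr")
    if not sol.success or max(abs(np.asarray(residual(sol.x)))) > 1e-6 * m.sd:
        raise ConfigurationError(
            f"marginal (mean={m.mean}, sd={m.sd}) is not attainable on [{lo}, {hi}]"
        )
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    return mu, sigma, (lo - mu) / sigma, (hi - mu) / sigma


@dataclass
class _OutputModel:
    """Calibrated response of one output (standardized units)."""

    coef: np.ndarray  # length-6 coefficients on standardized inputs
    interaction: float  # coefficient on the saturating interaction basis
    overload: float  # coefficient on the overload-inhibition basis
    m_inter: float  # calibration mean of the interaction basis
    m_over: float  # calibration mean of the overload basis
    regime_effect: dict[str, float]  # raw shifts, std units
    mix_shift: float  # configured-mix weighted mean of the raw shifts
    seasonal_amp: float  # sinusoid amplitude, std units (temperature only)
    noise_sd: float  # residual sd, std units


class PlantDataGenerator:
    """Calibrated sampler of synthetic plant records for one configuration."""

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config if config is not None else default_config()
        self._truncnorm_params = {
            name: _solve_truncnorm_params(m) for name, m in self.config.marginals
        }
        self._calibrate()

    # -- input sampling --------------------------------------------------------

    def _draw_regimes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Contiguous regime segments drawn from the regime mix."""
        mix = self.config.mix()
        probs = np.array([mix[r] for r in REGIMES])
        lo, hi = self.config.segment_hours
        steps_per_hour = 60 // SAMPLING_MINUTES
        out = np.empty(n, dtype=object)
        pos = 0
        while pos < n:
            length = int(rng.integers(lo, hi + 1)) * steps_per_hour
            regime = REGIMES[int(rng.choice(len(REGIMES), p=probs))]
            out[pos : pos + length] = regime
            pos += length
        return out[:n]

    def _draw_inputs(
        self, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Latent copula draw -> physical input matrix (n x 6) + regimes."""
        regimes = self._draw_regimes(n, rng)
        R = self.config.input_correlation()
        L = np.linalg.cholesky(R + 1e-12 * np.eye(R.shape[0]))
        Z = rng.standard_normal((n, len(INPUT_VARIABLES)))
        if n > 1:
            # centre the latent draw so campaign-wide sample means reproduce
            # the configured statistics without Monte-Carlo drift
            Z = Z - Z.mean(axis=0)
        Z = Z @ L.T

        # block-wise feed-quality step changes within load-fluctuation rows:
        # a common factor shared by feed solids and feed rate, variance-
        # preserving so the marginals stay on target.
        is_load = regimes == "load_fluctuation"
        if is_load.any() and self.config.load_factor_share > 0:
            v = self.config.load_factor_share
            lam_solids, lam_rate = self.config.load_factor_loadings
            steps_per_hour = 60 // SAMPLING_MINUTES
            lo, hi = self.config.load_block_hours
            block = np.zeros(n)
            pos = 0
            while pos < n:
                length = int(rng.integers(lo, hi + 1)) * steps_per_hour
                block[pos : pos + length] = rng.standard_normal()
                pos += length
            # step changes are deviations around the running feed level:
            # mean-zero across the load-fluctuation rows
            block[is_load] -= block[is_load].mean()
            for var, lam in (("feed_solids", lam_solids), ("feed_rate", lam_rate)):
                j = INPUT_VARIABLES.index(var)
                Z[is_load, j] = (
                    np.sqrt(1.0 - v * lam**2) * Z[is_load, j]
                    + lam * np.sqrt(v) * block[is_load]
                )

        X = np.empty_like(Z)
        for j, name in enumerate(INPUT_VARIABLES):
            mu, sigma, a, b = self._truncnorm_params[name]
            u = np.clip(ndtr(Z[:, j]), 1e-12, 1.0 - 1e-12)
            X[:, j] = truncnorm.ppf(u, a, b, loc=mu, scale=sigma)
        return X, regimes

    # -- calibration -----------------------------------------------------------

    def _seasonal_component(self, t: np.ndarray, n_span: int, regimes: np.ndarray) -> np.ndarray:
        """Slow sinusoid (period = dataset span) active on seasonal rows,
        centred over those rows so it is a pure deviation pattern."""
        s = np.where(regimes == "seasonal", np.sin(2.0 * np.pi * t / max(n_span, 1)), 0.0)
        active = regimes == "seasonal"
        if active.any():
            s[active] -= s[active].mean()
        return s

    def _calibrate(self) -> None:
        cfg = self.config
        rng = np.random.default_rng(_CALIBRATION_SEED)
        n = _CALIBRATION_SIZE
        X, regimes = self._draw_inputs(n, rng)
        self._std_mean = X.mean(axis=0)
        self._std_scale = X.std(axis=0, ddof=1)
        U = (X - self._std_mean) / self._std_scale

        i_s = INPUT_VARIABLES.index("feed_solids")
        i_o = INPUT_VARIABLES.index("organic_matter")
        i_f = INPUT_VARIABLES.index("feed_rate")

        # non-linear bases, residualized against the linear span of the
        # inputs so they carry pure non-linear structure: their variance
        # shares then add to the linear share without disturbing the
        # correlation targets
        bases = {}
        for name, w in (
            ("interaction", _interaction_basis(U[:, i_s], U[:, i_o])),
            ("overload", _overload_basis(U[:, i_s], U[:, i_f])),
        ):
            m_w = float(w.mean())
            beta, *_ = np.linalg.lstsq(U, w - m_w, rcond=None)
            resid = w - m_w - U @ beta
            bases[name] = {"mean": m_w, "beta": beta, "resid": resid, "var": float(resid.var())}

        t = np.arange(n)
        seas_unit = self._seasonal_component(t, n, regimes)

        targets = cfg.output_targets()
        mix = cfg.mix()
        inter_share = dict(cfg.interaction_share)
        over_share = dict(cfg.overload_share)
        noise_cfg = dict(cfg.noise_sd)
        raw_effects = {r: dict(effs) for r, effs in cfg.regime_effects}
        self._models: dict[str, _OutputModel] = {}

        def signed_coef(share: float, var: float) -> float:
            return float(np.sign(share) * np.sqrt(abs(share) / var)) if share else 0.0

        for out in OUTPUT_VARIABLES:
            m_out = cfg.marginal(out)
            support = [v for v in INPUT_VARIABLES if (v, out) in targets]
            r_S = np.array([targets[(v, out)] for v in support])
            S = [INPUT_VARIABLES.index(v) for v in support]

            raw = {r: raw_effects[r].get(out, 0.0) / m_out.sd for r in REGIMES}
            shift = sum(mix[r] * raw[r] for r in REGIMES)
            g = np.array([raw[r] - shift for r in regimes])

            amp = cfg.seasonal_temp_amplitude / m_out.sd if out == "temperature" else 0.0
            seas = amp * seas_unit

            a_int = signed_coef(inter_share.get(out, 0.0), bases["interaction"]["var"])
            a_over = signed_coef(over_share.get(out, 0.0), bases["overload"]["var"])

            for _attempt in range(4):
                extra = (
                    a_int * bases["interaction"]["resid"]
                    + a_over * bases["overload"]["resid"]
                    + g
                    + seas
                )
                coef_S = self._solve_coefficients(U, S, r_S, extra)
                coef = np.zeros(len(INPUT_VARIABLES))
                coef[S] = coef_S
                coef = coef - a_int * bases["interaction"]["beta"] - a_over * bases["overload"]["beta"]
                if out != "biogas_yield":
                    break
                # gas yield must stay monotone increasing in organic matter:
                # d y / d u_o = c_o + a_int * tanh(u_s) >= c_o - |a_int| > 0
                if coef[i_o] - abs(a_int) > 0:
                    break
                a_int *= 0.5
            y_sys = (
                U @ coef
                + a_int * (_interaction_basis(U[:, i_s], U[:, i_o]) - bases["interaction"]["mean"])
                + a_over * (_overload_basis(U[:, i_s], U[:, i_f]) - bases["overload"]["mean"])
                + g
                + seas
            )
            var_sys = float(y_sys.var(ddof=0))
            resid_var = 1.0 - var_sys
            if noise_cfg.get(out) is not None:
                noise_sd = noise_cfg[out] / m_out.sd
            else:
                if resid_var < 0.01:
                    raise ConfigurationError(
                        f"correlation targets for {out!r} leave no residual variance "
                        f"(systematic share {var_sys:.3f})"
                    )
                noise_sd = float(np.sqrt(resid_var))

            self._models[out] = _OutputModel(
                coef=coef,
                interaction=a_int,
                overload=a_over,
                m_inter=bases["interaction"]["mean"],
                m_over=bases["overload"]["mean"],
                regime_effect=raw,
                mix_shift=shift,
                seasonal_amp=amp,
                noise_sd=noise_sd,
            )

    @staticmethod
    def _solve_coefficients(
        U: np.ndarray, S: list[int], r_S: np.ndarray, extra: np.ndarray
    ) -> np.ndarray:
        """Moment matching: choose linear coefficients on the support set so
        the implied covariances with the standardized inputs equal the
        targets, accounting for the non-linear/regime/seasonal terms."""
        if not S:
            return np.zeros(0)
        U_S = U[:, S]
        C = np.cov(U_S, rowvar=False).reshape(len(S), len(S))
        c_extra = np.array(
            [np.cov(U_S[:, j], extra)[0, 1] for j in range(len(S))]
        )
        return np.linalg.solve(C, r_S - c_extra)

    # -- public sampling API ---------------------------------------------------

    def standardize_inputs(self, X: np.ndarray) -> np.ndarray:
        return (X - self._std_mean) / self._std_scale

    def response(
        self,
        U: np.ndarray,
        regimes: np.ndarray,
        seasonal_unit: np.ndarray | None = None,
        regime_centering: str = "configured",
    ) -> dict[str, np.ndarray]:
        """Noise-free outputs (output units) from standardized inputs.

        ``regime_centering`` controls how the per-regime shifts are made
        mean-zero: against the configured regime mix (the reference frame of
        :meth:`true_response`) or against the realized proportions of
        ``regimes`` (used when sampling whole campaigns, so campaign means
        stay on target).
        """
        i_s = INPUT_VARIABLES.index("feed_solids")
        i_o = INPUT_VARIABLES.index("organic_matter")
        i_f = INPUT_VARIABLES.index("feed_rate")
        out = {}
        for name in OUTPUT_VARIABLES:
            m = self._models[name]
            marg = self.config.marginal(name)
            y = (
                U @ m.coef
                + m.interaction * (_interaction_basis(U[:, i_s], U[:, i_o]) - m.m_inter)
                + m.overload * (_overload_basis(U[:, i_s], U[:, i_f]) - m.m_over)
            )
            g = np.array([m.regime_effect[r] for r in regimes])
            if regime_centering == "realized":
                y = y + (g - g.mean())
            else:
                y = y + (g - m.mix_shift)
            if seasonal_unit is not None and m.seasonal_amp:
                y = y + m.seasonal_amp * seasonal_unit
            out[name] = marg.mean + marg.sd * y
        return out

    def generate(self, n: int, seed: int | None = None) -> pd.DataFrame:
        """Sample ``n`` records at 5-minute cadence (faults included)."""
        if n < 1:
            raise ValueError(f"n must be >= 1, got {n}")
        seed = self.config.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        X, regimes = self._draw_inputs(n, rng)
        U = self.standardize_inputs(X)
        seas_unit = self._seasonal_component(np.arange(n), n, regimes)
        outputs = self.response(U, regimes, seas_unit, regime_centering="realized")
        for name in OUTPUT_VARIABLES:
            m = self._models[name]
            marg = self.config.marginal(name)
            eps = rng.standard_normal(n)
            if n > 1:
                eps -= eps.mean()
            outputs[name] = outputs[name] + marg.sd * m.noise_sd * eps
            if marg.lower is not None:
                outputs[name] = np.maximum(outputs[name], marg.lower)

        df = pd.DataFrame(
            {
                "timestamp": pd.date_range(
                    START_TIMESTAMP, periods=n, freq=f"{SAMPLING_MINUTES}min"
                ),
                **{v: X[:, j] for j, v in enumerate(INPUT_VARIABLES)},
                **{v: outputs[v] for v in OUTPUT_VARIABLES},
                "regime": regimes.astype(str),
                "fault_flag": np.zeros(n, dtype=bool),
            }
        )
        if self.config.fault_rate > 0:
            df = inject_faults(df, self.config.fault_rate, seed=(seed + 1) % (2**31))
        return df

    def true_response(
        self,
        feed_solids,
        organic_matter,
        feed_rate,
        regime: str = "steady",
    ) -> tuple:
        """Deterministic response kernel at nominal auxiliary conditions.

        Accepts scalars or arrays; validates inputs against the physical
        ranges of the configuration.
        """
        if regime not in REGIMES:
            raise ValueError(f"unknown regime {regime!r}")
        vals = {
            "feed_solids": np.asarray(feed_solids, dtype=float),
            "organic_matter": np.asarray(organic_matter, dtype=float),
            "feed_rate": np.asarray(feed_rate, dtype=float),
        }
        scalar = all(v.ndim == 0 for v in vals.values())
        for name, v in vals.items():
            m = self.config.marginal(name)
            lo = -np.inf if m.lower is None else m.lower
            hi = np.inf if m.upper is None else m.upper
            if np.any(v < lo) or np.any(v > hi):
                raise ValueError(f"{name} outside physical range [{lo}, {hi}]")
        n = int(np.broadcast(*vals.values()).size)
        U = np.zeros((n, len(INPUT_VARIABLES)))
        for name in CORE_VARIABLES:
            j = INPUT_VARIABLES.index(name)
            U[:, j] = (np.broadcast_to(vals[name], (n,)) - self._std_mean[j]) / self._std_scale[j]
        regimes = np.array([regime] * n, dtype=object)
        out = self.response(U, regimes)
        result = tuple(out[v][0] if scalar else out[v] for v in OUTPUT_VARIABLES)
        return result


@functools.lru_cache(maxsize=8)
def _generator_for(config: GeneratorConfig) -> PlantDataGenerator:
    return PlantDataGenerator(config)


def generate_records(config: GeneratorConfig | None = None, n: int = 10_000) -> pd.DataFrame:
    """Generate ``n`` synthetic plant records under ``config`` (cached calibration)."""
    config = config if config is not None else default_config()
    return _generator_for(config).generate(n)


def true_response(
    feed_solids,
    organic_matter,
    feed_rate,
    regime: str = "steady",
    config: GeneratorConfig | None = None,
):
    """Noise-free (biogas_yield, temperature, vfa) response kernel."""
    config = config if config is not None else default_config()
    return _generator_for(config).true_response(feed_solids, organic_matter, feed_rate, regime)


_FAULT_MODES = ("temperature", "feed_solids", "organic_matter", "biogas_yield")


def inject_faults(table: pd.DataFrame, fault_rate: float, seed: int = 0) -> pd.DataFrame:
    """Overwrite a random ``round(n * fault_rate)`` subset of records with
    sensor-fault values, each violating exactly one cleaning limit
    (temperature > 80, feed solids > 40, organic matter > 50, or negative
    gas yield), and set their ``fault_flag``."""
    if not 0.0 <= fault_rate <= 0.1:
        raise ValueError(f"fault_rate must lie in [0, 0.1], got {fault_rate}")
    out = table.copy()
    n = len(out)
    n_faults = int(np.floor(n * fault_rate + 0.5))
    if n_faults == 0:
        return out
    rng = np.random.default_rng(seed)
    rows = rng.choice(n, size=n_faults, replace=False)
    modes = rng.integers(0, len(_FAULT_MODES), size=n_faults)
    values = {
        "temperature": rng.uniform(81.0, 95.0, size=n_faults),
        "feed_solids": rng.uniform(40.5, 50.0, size=n_faults),
        "organic_matter": rng.uniform(50.5, 60.0, size=n_faults),
        "biogas_yield": rng.uniform(-5.0, -0.1, size=n_faults),
    }
    for k, (row, mode) in enumerate(zip(rows, modes)):
        var = _FAULT_MODES[mode]
        out.iloc[row, out.columns.get_loc(var)] = values[var][k]
    out.iloc[rows, out.columns.get_loc("fault_flag")] = True
    return out


def write_records(table: pd.DataFrame, path) -> None:
    """Write records as CSV with ISO-8601 timestamps."""
    out = table.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read a record CSV written by :func:`write_records`."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if "fault_flag" in df.columns:
        df["fault_flag"] = df["fault_flag"].astype(bool)
    return df
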