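"""Cleaning, scaling, splitting and correlation-based feature selection.

One shared protocol for every predictor: engineering-limit outlier
removal, min-max scaling fitted on the training block only, a 7:2:1
train/validation/test split (chronological by default), a two-sample
Kolmogorov-Smirnov check of split similarity, and Pearson-correlation
feature screening against the prediction target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateScaleError
from .synth import OUTPUT_VARIABLES, PROCESS_VARIABLES

__all__ = [
    "CleaningLimits",
    "NormalizationParams",
    "SplitSpec",
    "remove_outliers",
    "minmax_fit",
    "minmax_apply",
    "minmax_invert",
    "split",
    "ks_similarity",
    "pearson_matrix",
    "select_features",
]


@dataclass(frozen=True)
class CleaningLimits:
    """Per-variable physical bounds; a record violating any bound is removed.

    Defaults are the plant's cleaning rules: reactor temperature cannot
    exceed 80 degC, feed solids 40 %, organic matter 50 %, and gas yield
    cannot be negative.
    """

    limits: tuple[tuple[str, tuple[float | None, float | None]], ...] = (
        ("temperature", (None, 80.0)),
        ("feed_solids", (None, 40.0)),
        ("organic_matter", (None, 50.0)),
        ("biogas_yield", (0.0, None)),
    )

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.limits:
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError(f"cleaning limits for {var!r}: lower must be < upper")

    def as_dict(self) -> dict[str, tuple[float | None, float | None]]:
        return dict(self.limits)


def remove_outliers(
    table: pd.DataFrame, limits: CleaningLimits | None = None
) -> tuple[pd.DataFrame, int]:
    """Drop records violating any cleaning limit (or with missing fields).

    Returns the surviving records in their original order together with
    the number removed.  Idempotent; an empty table passes through.
    """
    limits = limits if limits is not None else CleaningLimits()
    if table.empty:
        return table.copy(), 0
    keep = pd.Series(True, index=table.index)
    present = [c for c in table.columns if c in PROCESS_VARIABLES]
    if present:
        keep &= table[present].notna().all(axis=1)
    for var, (lo, hi) in limits.as_dict().items():
        if var not in table.columns:
            continue
        if lo is not None:
            keep &= table[var] >= lo
        if hi is not None:
            keep &= table[var] <= hi
    cleaned = table.loc[keep].copy()
    return cleaned, int(len(table) - len(cleaned))


@dataclass(frozen=True)
class NormalizationParams:
    """Per-variable min/max fitted on the training block only."""

    x_min: tuple[tuple[str, float], ...]
    x_max: tuple[tuple[str, float], ...]

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.x_min)

    def bounds(self, variable: str) -> tuple[float, float]:
        lo = dict(self.x_min)[variable]
        hi = dict(self.x_max)[variable]
        return lo, hi

    def to_dict(self) -> dict:
        return {"x_min": dict(self.x_min), "x_max": dict(self.x_max)}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(tuple(d["x_min"].items()), tuple(d["x_max"].items()))


def minmax_fit(train: pd.DataFrame, variables: list[str] | None = None) -> NormalizationParams:
    """Fit min-max scaling parameters x_min/x_max on training data."""
    if train.empty:
        raise ValueError("cannot fit normalization on an empty table")
    variables = (
        list(variables)
        if variables is not None
        else [c for c in train.columns if c in PROCESS_VARIABLES]
    )
    mins, maxs = [], []
    for var in variables:
        lo, hi = float(train[var].min()), float(train[var].max())
        if not hi > lo:
            raise DegenerateScaleError(f"variable {var!r} is constant (x_max == x_min == {lo})")
        mins.append((var, lo))
        maxs.append((var, hi))
    return NormalizationParams(tuple(mins), tuple(maxs))


def minmax_apply(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """x' = (x - x_min) / (x_max - x_min), per fitted variable.

    Values outside the training range map outside [0, 1]; no clipping.
    Columns without fitted parameters pass through unchanged.
    """
    out = table.copy()
    for var in params.variables:
        if var not in out.columns:
            raise KeyError(f"variable {var!r} not present in table")
        lo, hi = params.bounds(var)
        out[var] = (out[var] - lo) / (hi - lo)
    return out


def minmax_invert(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Algebraic inverse of :func:`minmax_apply`."""
    out = table.copy()
    for var in params.variables:
        if var not in out.columns:
            raise KeyError(f"variable {var!r} not present in table")
        lo, hi = params.bounds(var)
        out[var] = out[var] * (hi - lo) + lo
    return out


@dataclass(frozen=True)
class SplitSpec:
    """7:2:1 train/validation/test split specification."""

    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    mode: str = "chronological"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios) or abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must be positive and sum to 1")
        if self.mode not in ("chronological", "random"):
            raise ValueError(f"unknown split mode {self.mode!r}")


def split(
    table: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition records into train/validation/test blocks.

    Chronological mode sorts by timestamp and takes contiguous blocks;
    random mode permutes rows with the spec's seed first.  Sizes are
    ``floor(r_train * n)`` / ``floor(r_val * n)`` / remainder.
    """
    spec = spec if spec is not None else SplitSpec()
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    if spec.mode == "chronological":
        ordered = (
            table.sort_values("timestamp", kind="stable")
            if "timestamp" in table.columns
            else table
        )
    else:
        rng = np.random.default_rng(spec.seed)
        ordered = table.iloc[rng.permutation(n)]
    n_train = int(np.floor(spec.ratios[0] * n))
    n_val = int(np.floor(spec.ratios[1] * n))
    train = ordered.iloc[:n_train].copy()
    val = ordered.iloc[n_train : n_train + n_val].copy()
    test = ordered.iloc[n_train + n_val :].copy()
    return train, val, test


def ks_similarity(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("both samples must contain at least 5 observations")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def pearson_matrix(train: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix of the training block."""
    variables = (
        list(variables)
        if variables is not None
        else [c for c in train.columns if c in PROCESS_VARIABLES]
    )
    if len(train) < 3:
        raise ValueError("need at least 3 training rows for correlations")
    for var in variables:
        if float(train[var].std()) == 0.0:
            raise DegenerateScaleError(f"correlation undefined: variable {var!r} is constant")
    return train[variables].corr(method="pearson")


def select_features(
    matrix: pd.DataFrame,
    target: str,
    core_threshold: float = 0.40,
    candidates: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Split candidate inputs into core (|r| >= threshold vs the target)
    and auxiliary variables, preserving the matrix column order.

    By default the candidates are the measured input variables present in
    the matrix; the prediction outputs never compete as predictors.
    """
    if target not in matrix.columns:
        raise KeyError(f"target {target!r} not in correlation matrix")
    if candidates is None:
        candidates = [c for c in matrix.columns if c not in OUTPUT_VARIABLES]
    core, auxiliary = [], []
    for var in candidates:
        if var == target:
            continue
        (core if abs(matrix.loc[var, target]) >= core_threshold else auxiliary).append(var)
    return core, auxiliary
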