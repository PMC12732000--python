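"""Classification/regression metrics, cross-validation and attribution.

Precision/recall/F1 from the confusion counts, AUROC with mid-rank tie
handling, RMSE and R-squared, contiguous-in-time five-fold
cross-validation, rolling-window evaluation, impurity-based random
forest importance shares and permutation-based delta-RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score

from .models import FittedModel, RFSpec, fit_model, _as_frame, _loc

__all__ = [
    "ClassificationMetrics",
    "RegressionMetrics",
    "classification_metrics",
    "regression_metrics",
    "kfold_cv",
    "rolling_window_eval",
    "rf_importance",
    "permutation_delta_rmse",
]


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class RegressionMetrics:
    rmse: float
    r2: float


def classification_metrics(labels, predictions, scores) -> ClassificationMetrics:
    """Confusion-count metrics for +/-1 labels plus rank-based AUROC.

    Zero-denominator metrics are reported as NaN (undefined), never 0.
    AUROC requires both classes present.
    """
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not (len(labels) == len(predictions) == len(scores)):
        raise ValueError("labels, predictions and scores must be aligned")
    if not set(np.unique(labels)) <= {-1, 1}:
        raise ValueError("labels must be in {+1, -1}")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == -1) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == -1)))
    tn = int(np.sum((labels == -1) & (predictions == -1)))
    n = tp + fp + fn + tn
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    auroc = float(roc_auc_score(labels, scores))
    return ClassificationMetrics(
        accuracy=(tp + tn) / n,
        precision=precision,
        recall=recall,
        f1=f1,
        auroc=auroc,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def regression_metrics(y, y_hat) -> RegressionMetrics:
    """RMSE (target units) and R-squared = 1 - SS_res / SS_tot.

    R-squared is undefined (NaN) for constant ``y``; it is flagged, not
    reported as 0.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) != len(y_hat):
        raise ValueError("y and y_hat must be aligned")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0.0 else float("nan")
    return RegressionMetrics(rmse=float(np.sqrt(ss_res / len(y))), r2=r2)


def kfold_cv(spec, X: pd.DataFrame, y, k: int = 5, seed: int = 0, shuffle: bool = False):
    """k-fold cross-validation; folds contiguous in time by default.

    Every record is scored exactly once out-of-fold.  Returns
    ``(per_fold, mean, sd)`` where ``per_fold`` is a list of metric
    objects (regression or classification depending on the task).
    """
    n = len(X)
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    order = np.arange(n)
    if shuffle:
        order = np.random.default_rng(seed).permutation(n)
    bounds = np.linspace(0, n, k + 1).astype(int)
    per_fold = []
    for i in range(k):
        test_idx = order[bounds[i] : bounds[i + 1]]
        train_idx = np.setdiff1d(order, test_idx)
        model = fit_model(spec, X.iloc[train_idx], _loc(y, train_idx))
        pred = model.predict(X.iloc[test_idx])
        if model.task == "classify":
            truth = np.asarray(_loc(y, test_idx))
            per_fold.append(
                classification_metrics(truth, pred["label"].to_numpy(), pred["score"].to_numpy())
            )
        else:
            truth = _as_frame(_loc(y, test_idx))
            t0 = truth.columns[0]
            y_true, y_pred = truth[t0].to_numpy(), pred[t0].to_numpy()
            if len(y_true) == 1:  # leave-one-out fold
                per_fold.append(
                    RegressionMetrics(rmse=float(abs(y_true[0] - y_pred[0])), r2=float("nan"))
                )
            else:
                per_fold.append(regression_metrics(y_true, y_pred))
    key = "rmse" if isinstance(per_fold[0], RegressionMetrics) else "accuracy"
    vals = np.array([getattr(m, key) for m in per_fold])
    return per_fold, float(vals.mean()), float(vals.std(ddof=1))


def rolling_window_eval(
    spec, X: pd.DataFrame, y, window: int, step: int
) -> pd.DataFrame:
    """Train on [t, t+window), test on [t+window, t+window+step), advance
    by ``step``; no test row ever precedes its training window."""
    n = len(X)
    if window + step > n:
        raise ValueError("window + step must not exceed the number of rows")
    rows = []
    start = 0
    while start + window + step <= n:
        tr = slice(start, start + window)
        te = slice(start + window, start + window + step)
        model = fit_model(spec, X.iloc[tr], _loc(y, np.arange(n)[tr]))
        pred = model.predict(X.iloc[te])
        truth = _as_frame(_loc(y, np.arange(n)[te]))
        t0 = truth.columns[0]
        m = regression_metrics(truth[t0].to_numpy(), pred[t0].to_numpy())
        rows.append({"window_start": start, "rmse": m.rmse, "r2": m.r2})
        start += step
    return pd.DataFrame(rows)


def rf_importance(model: FittedModel, target: str | None = None) -> pd.Series:
    """Impurity-decrease importances normalized to shares summing to 1."""
    if not isinstance(model.spec, RFSpec):
        raise TypeError("rf_importance requires a random-forest model")
    est = model.estimators
    if isinstance(est, dict):
        target = target if target is not None else model.target_names[0]
        est = est[target]
    if not isinstance(est, (RandomForestRegressor, RandomForestClassifier)):
        raise TypeError("rf_importance requires a fitted random forest")
    imp = np.asarray(est.feature_importances_, dtype=float)
    shares = imp / imp.sum()
    return pd.Series(shares, index=list(model.feature_names), name="importance_share")


def permutation_delta_rmse(
    model: FittedModel,
    X: pd.DataFrame,
    y,
    feature: str,
    n_perm: int = 10,
    seed: int = 0,
    target: str | None = None,
) -> float:
    """Mean increase in RMSE after permuting one feature column.

    Positive values mean the model relies on the feature; features the
    model ignores give values near zero.
    """
    if feature not in X.columns:
        raise KeyError(f"feature {feature!r} not in X")
    target = target if target is not None else model.target_names[0]
    yf = _as_frame(y)
    y_arr = np.asarray(yf[target] if target in yf.columns else yf.iloc[:, 0], dtype=float)
    col = "label" if model.task == "classify" else target
    base_pred = model.predict(X)[col].to_numpy(dtype=float)
    base_rmse = float(np.sqrt(np.mean((y_arr - base_pred) ** 2)))
    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(n_perm):
        Xp = X.copy()
        Xp[feature] = rng.permutation(Xp[feature].to_numpy())
        pred = model.predict(Xp)[col].to_numpy(dtype=float)
        deltas.append(float(np.sqrt(np.mean((y_arr - pred) ** 2))) - base_rmse)
    return float(np.mean(deltas))
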