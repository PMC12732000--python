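"""The three soft-sensor model families under one fitting protocol.

* Support vector machine: RBF-kernel classification of high/low gas
  yield and epsilon-insensitive regression (delegated to scikit-learn).
* Random forest: bootstrap ensembles with majority voting
  (classification) / ensemble mean (regression), one forest per target
  (delegated to scikit-learn).
* Artificial neural network: a fully connected feed-forward network
  (default [128, 64], ReLU) predicting biogas yield, temperature and
  VFA jointly, trained here with Adam on the penalized objective
  ``mean_i ||y_hat_i - y_i||^2 + lambda ||theta||^2`` with early
  stopping on validation loss and best-weight restoration.

Classification uses the plant's engineering threshold: records with gas
yield >= 70 m3/t are labelled +1 (high), below -1 (low).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.svm import SVC, SVR

__all__ = [
    "HIGH_YIELD_THRESHOLD",
    "SVMSpec",
    "RFSpec",
    "ANNSpec",
    "FittedModel",
    "label_high_yield",
    "fit_model",
    "predict",
    "grid_search",
]

HIGH_YIELD_THRESHOLD = 70.0  # m3/t, engineering lower bound of acceptable yield


def label_high_yield(biogas_yield):
    """+1 for gas yield >= 70 m3/t, -1 below; scalar or array-like."""
    y = np.asarray(biogas_yield, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("biogas yield must be finite")
    labels = np.where(y >= HIGH_YIELD_THRESHOLD, 1, -1)
    return int(labels) if y.ndim == 0 else labels


@dataclass(frozen=True)
class SVMSpec:
    """RBF-kernel SVM; ``task`` selects classification or regression."""

    task: str = "regress"
    C: float = 10.0
    gamma: float = 0.05
    epsilon: float = 0.1  # insensitive-zone half-width, scaled units

    def __post_init__(self) -> None:
        if self.task not in ("classify", "regress"):
            raise ValueError(f"unknown SVM task {self.task!r}")
        if self.C <= 0 or self.gamma <= 0 or self.epsilon < 0:
            raise ValueError("require C > 0, gamma > 0, epsilon >= 0")


@dataclass(frozen=True)
class RFSpec:
    """Random forest: B trees, depth limit, mtry features per split."""

    n_trees: int = 100
    max_depth: int = 18
    mtry: int = 2
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1 or self.mtry < 1:
            raise ValueError("require n_trees >= 1, max_depth >= 1, mtry >= 1")


@dataclass(frozen=True)
class ANNSpec:
    """Feed-forward network trained with Adam on the L2-penalized MSE."""

    hidden_sizes: tuple[int, ...] = (128, 64)
    activation: str = "relu"
    learning_rate: float = 0.001
    batch_size: int = 64
    l2_lambda: float = 0.0001
    max_epochs: int = 500
    early_stop_patience: int = 20
    seed: int = 42

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        if self.learning_rate <= 0 or self.l2_lambda < 0:
            raise ValueError("require learning_rate > 0 and l2_lambda >= 0")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")


#: compact architecture variant discussed alongside the default
ANN_COMPACT = ANNSpec(hidden_sizes=(32, 32))


class _MLP:
    """Minimal fully connected network with Adam and L2 penalty.

    The training objective is the one the fitting protocol specifies:
    ``L = (1/N) sum_i ||y_hat_i - y_i||^2 + lambda * ||theta||^2``
    where theta collects all weights and biases.  Early stopping
    monitors the un-penalized validation MSE and restores the best
    weights seen.
    """

    def __init__(self, n_in: int, n_out: int, spec: ANNSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        sizes = [n_in, *spec.hidden_sizes, n_out]
        self.W = [
            rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        self.b = [np.zeros(b) for b in sizes[1:]]
        self._rng = rng
        self.history: dict[str, list[float]] = {"train_objective": [], "val_mse": []}
        self.best_epoch: int | None = None

    def _act(self, z):
        return np.maximum(z, 0.0) if self.spec.activation == "relu" else np.tanh(z)

    def _act_grad(self, z, a):
        return (z > 0).astype(float) if self.spec.activation == "relu" else 1.0 - a**2

    def forward(self, X):
        zs, acts = [], [X]
        a = X
        for k, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            zs.append(z)
            a = z if k == len(self.W) - 1 else self._act(z)
            acts.append(a)
        return zs, acts

    def predict(self, X):
        return self.forward(X)[1][-1]

    def _objective(self, X, y):
        err = self.predict(X) - y
        data = float(np.mean(np.sum(err**2, axis=1)))
        reg = sum(float(np.sum(W**2)) for W in self.W) + sum(
            float(np.sum(b**2)) for b in self.b
        )
        return data + self.spec.l2_lambda * reg

    def fit(self, X, y, X_val, y_val):
        spec = self.spec
        n = len(X)
        params = self.W + self.b
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_val = np.inf
        best_weights = None
        patience_left = spec.early_stop_patience

        for epoch in range(spec.max_epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                Xb, yb = X[idx], y[idx]
                zs, acts = self.forward(Xb)
                # d(data)/d(out) for the mean over the batch
                delta = 2.0 * (acts[-1] - yb) / len(Xb)
                gW, gb = [None] * len(self.W), [None] * len(self.b)
                for k in range(len(self.W) - 1, -1, -1):
                    gW[k] = acts[k].T @ delta + 2.0 * spec.l2_lambda * self.W[k]
                    gb[k] = delta.sum(axis=0) + 2.0 * spec.l2_lambda * self.b[k]
                    if k > 0:
                        delta = (delta @ self.W[k].T) * self._act_grad(zs[k - 1], acts[k])
                grads = gW + gb
                step += 1
                lr_t = spec.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi += (1 - beta1) * (g - mi)
                    vi += (1 - beta2) * (g**2 - vi)
                    p -= lr_t * mi / (np.sqrt(vi) + eps)

            self.history["train_objective"].append(self._objective(X, y))
            val_err = self.predict(X_val) - y_val
            val_mse = float(np.mean(np.sum(val_err**2, axis=1)))
            self.history["val_mse"].append(val_mse)
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_weights = ([W.copy() for W in self.W], [b.copy() for b in self.b])
                self.best_epoch = epoch
                patience_left = spec.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
        if best_weights is not None:
            self.W, self.b = best_weights
        return self


@dataclass
class FittedModel:
    """A trained predictor with its spec and data contract.

    Behaves like a results object: carries the spec, the fitted
    parameters, the exact input-variable list required at prediction
    time, the targets, optional normalization-parameter reference and
    the training history (ANN).
    """

    spec: Any
    task: str  # "classify" | "regress"
    feature_names: tuple[str, ...]
    target_names: tuple[str, ...]
    estimators: Any  # per-target dict, single estimator, or _MLP
    normalization: Any = None  # NormalizationParams used for the inputs
    history: dict | None = None

    def _check_columns(self, X: pd.DataFrame) -> np.ndarray:
        if tuple(X.columns) != self.feature_names:
            raise ValueError(
                f"prediction inputs must be exactly {list(self.feature_names)} "
                f"(got {list(X.columns)})"
            )
        return X.to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """One prediction per row; classification adds a decision score."""
        arr = self._check_columns(X)
        if self.task == "classify":
            est = self.estimators
            if isinstance(est, RandomForestClassifier):
                # mean class vote in [-1, 1]
                score = est.predict_proba(arr) @ est.classes_
            else:
                score = est.decision_function(arr)
            return pd.DataFrame(
                {"label": est.predict(arr).astype(int), "score": score}, index=X.index
            )
        if isinstance(self.estimators, _MLP):
            out = self.estimators.predict(arr)
            return pd.DataFrame(out, columns=list(self.target_names), index=X.index)
        return pd.DataFrame(
            {t: self.estimators[t].predict(arr) for t in self.target_names}, index=X.index
        )

    def summary(self) -> str:
        lines = [
            f"{type(self.spec).__name__} ({self.task})",
            f"  inputs : {', '.join(self.feature_names)}",
            f"  targets: {', '.join(self.target_names)}",
            f"  spec   : {self.spec}",
        ]
        if self.history and self.history.get("train_objective"):
            lines.append(
                f"  epochs : {len(self.history['train_objective'])}"
                f" (best val MSE {min(self.history['val_mse']):.5f})"
            )
        return "\n".join(lines)


def _as_frame(y) -> pd.DataFrame:
    return y.to_frame() if isinstance(y, pd.Series) else y


def _is_labels(y) -> bool:
    vals = set(np.unique(np.asarray(y)))
    return vals <= {-1, 1}


def fit_model(spec, X: pd.DataFrame, y, validation=None, normalization=None) -> FittedModel:
    """Train one model under the shared protocol.

    ``X`` must already be scaled with the training normalization; ``y``
    is a Series (single target / labels) or DataFrame (ANN multi-target).
    ``validation`` is an optional ``(X_val, y_val)`` pair used by the ANN
    for early stopping (a chronological 10 % tail of the training block
    is carved off when absent).
    """
    if len(X) != len(y):
        raise ValueError(f"row mismatch: X has {len(X)} rows, y has {len(y)}")
    features = tuple(X.columns)
    arr = X.to_numpy(dtype=float)

    if isinstance(spec, SVMSpec):
        if spec.task == "classify":
            labels = np.asarray(y, dtype=int)
            if len(np.unique(labels)) < 2:
                raise ValueError("classification training data contains a single class")
            est = SVC(kernel="rbf", C=spec.C, gamma=spec.gamma)
            est.fit(arr, labels)
            return FittedModel(spec, "classify", features, ("label",), est, normalization)
        yf = _as_frame(y)
        ests = {}
        for t in yf.columns:
            est = SVR(kernel="rbf", C=spec.C, gamma=spec.gamma, epsilon=spec.epsilon)
            est.fit(arr, yf[t].to_numpy(dtype=float))
            ests[t] = est
        return FittedModel(spec, "regress", features, tuple(yf.columns), ests, normalization)

    if isinstance(spec, RFSpec):
        if spec.mtry > len(features):
            raise ValueError("mtry exceeds the number of features")
        if isinstance(y, pd.Series) and _is_labels(y):
            labels = np.asarray(y, dtype=int)
            if len(np.unique(labels)) < 2:
                raise ValueError("classification training data contains a single class")
            est = RandomForestClassifier(
                n_estimators=spec.n_trees,
                max_depth=spec.max_depth,
                max_features=spec.mtry,
                random_state=spec.seed,
            )
            est.fit(arr, labels)
            return FittedModel(spec, "classify", features, ("label",), est, normalization)
        yf = _as_frame(y)
        ests = {}
        for k, t in enumerate(yf.columns):
            est = RandomForestRegressor(
                n_estimators=spec.n_trees,
                max_depth=spec.max_depth,
                max_features=spec.mtry,
                random_state=spec.seed + k,
            )
            est.fit(arr, yf[t].to_numpy(dtype=float))
            ests[t] = est
        return FittedModel(spec, "regress", features, tuple(yf.columns), ests, normalization)

    if isinstance(spec, ANNSpec):
        yf = _as_frame(y)
        y_arr = yf.to_numpy(dtype=float)
        if validation is not None:
            X_val, y_val = validation
            Xv = X_val.to_numpy(dtype=float)
            yv = _as_frame(y_val).to_numpy(dtype=float)
            X_tr, y_tr = arr, y_arr
        else:
            cut = max(1, int(0.9 * len(arr)))
            X_tr, y_tr = arr[:cut], y_arr[:cut]
            Xv, yv = arr[cut:], y_arr[cut:]
            if len(Xv) == 0:
                Xv, yv = X_tr, y_tr
        net = _MLP(arr.shape[1], y_arr.shape[1], spec)
        net.fit(X_tr, y_tr, Xv, yv)
        return FittedModel(
            spec, "regress", features, tuple(yf.columns), net, normalization, net.history
        )

    raise TypeError(f"unknown spec type {type(spec).__name__}")


def predict(model: FittedModel, X: pd.DataFrame) -> pd.DataFrame:
    """Functional alias for :meth:`FittedModel.predict`."""
    return model.predict(X)


def grid_search(
    spec_template,
    grid: dict[str, list],
    X: pd.DataFrame,
    y,
    folds: int = 5,
    seed: int = 0,
) -> tuple[Any, pd.DataFrame]:
    """Exhaustive grid evaluation by k-fold cross-validation.

    Folds are contiguous in time (consistent with the chronological
    protocol).  The score is mean out-of-fold MSE for regression and
    mean error rate for classification; ties break in first-in-grid
    order.  Returns the winning spec and the full score table.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    n = len(X)
    if n < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV")
    bounds = np.linspace(0, n, folds + 1).astype(int)
    rows = []
    best = None
    keys = list(grid.keys())
    for values in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, values))
        spec = replace(spec_template, **params)
        losses = []
        for k in range(folds):
            lo, hi = bounds[k], bounds[k + 1]
            mask = np.zeros(n, dtype=bool)
            mask[lo:hi] = True
            model = fit_model(spec, X.iloc[~mask], _loc(y, ~mask))
            pred = model.predict(X.iloc[mask])
            if model.task == "classify":
                losses.append(float(np.mean(pred["label"].to_numpy() != np.asarray(_loc(y, mask)))))
            else:
                truth = _as_frame(_loc(y, mask)).to_numpy(dtype=float)
                losses.append(float(np.mean((pred.to_numpy() - truth) ** 2)))
        score = float(np.mean(losses))
        rows.append({**params, "cv_loss": score})
        if best is None or score < best[0]:
            best = (score, spec)
    return best[1], pd.DataFrame(rows)


def _loc(y, mask):
    return y.iloc[mask] if hasattr(y, "iloc") else y[mask]
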