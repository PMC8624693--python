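"""Regression performance measures and the k-fold cross-validation harness.

Four measures are reported everywhere, matching conventional regression
evaluation of predicted volumes y_hat against spirometer ground truth y:

* ``R^2 = 1 - SS_res / SS_total`` with ``SS_total = sum (y_i - y_bar)^2`` and
  ``SS_res = sum (y_i - y_hat_i)^2``
* ``MSE = (1/n) sum (y_i - y_hat_i)^2``
* ``RMSE = sqrt(MSE)``
* ``MAE = (1/n) sum |y_i - y_hat_i|``

Cross-validation splits at the *recording* level, never the sample level, so
no recording contributes to both a training and a test fold.  The headline
metrics are computed on the pooled out-of-fold prediction vector; per-fold
metrics and their means are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .errors import ConfigurationError, InsufficientDataError, UndefinedMetricError
from .regress import RegressionDataset, fit

__all__ = [
    "EvaluationReport",
    "r_squared",
    "mse",
    "rmse",
    "mae",
    "cross_validate",
    "evaluate_all",
]


def _check_pair(y, y_hat, min_len: int = 1) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ConfigurationError(
            f"length mismatch: {y.shape[0]} measured vs {y_hat.shape[0]} predicted"
        )
    if y.shape[0] < min_len:
        raise InsufficientDataError(
            f"need at least {min_len} value(s), got {y.shape[0]}"
        )
    return y, y_hat


def r_squared(y, y_hat) -> float:
    """Coefficient of determination, 1 - SS_res / SS_total.

    Equals 1 only for a perfect fit; 0 for the constant-mean predictor; may
    be negative for a predictor worse than the mean.  Undefined when the
    measured values are constant (SS_total = 0).
    """
    y, y_hat = _check_pair(y, y_hat, min_len=2)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total == 0.0:
        raise UndefinedMetricError("R-squared is undefined for constant measured values")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_total


def mse(y, y_hat) -> float:
    """Mean squared error, litres squared."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.mean((y - y_hat) ** 2))


def rmse(y, y_hat) -> float:
    """Root mean squared error, litres."""
    return float(np.sqrt(mse(y, y_hat)))


def mae(y, y_hat) -> float:
    """Mean absolute error, litres."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


@dataclass
class EvaluationReport:
    """Cross-validated performance of one regressor.

    Headline metrics (``r_squared`` .. ``mae``) are pooled over all
    out-of-fold predictions; ``per_fold`` carries the same four metrics per
    fold (R-squared is NaN for folds whose measured values are constant),
    and ``fold_mean`` their across-fold averages.
    """

    method: str
    n: int
    k: int
    fold_seed: int
    r_squared: float
    mse: float
    rmse: float
    mae: float
    per_fold: list[dict] = field(default_factory=list)
    fold_mean: dict = field(default_factory=dict)
    y_true: np.ndarray = field(default_factory=lambda: np.array([]))
    y_pred: np.ndarray = field(default_factory=lambda: np.array([]))
    y_mean: float = float("nan")
    ss_res: float = float("nan")
    ss_total: float = float("nan")

    def summary(self) -> dict:
        """The four headline metrics as a plain dict (JSON-friendly)."""
        return {
            "method": self.method,
            "n": self.n,
            "k": self.k,
            "r_squared": self.r_squared,
            "mse": self.mse,
            "rmse": self.rmse,
            "mae": self.mae,
        }


def cross_validate(
    dataset: RegressionDataset,
    method: str = "decision_tree",
    k: int = 10,
    seed: int = 0,
    hyperparameters: dict | None = None,
) -> EvaluationReport:
    """k-fold cross-validation of one regressor at the recording level.

    Recordings are shuffled with ``seed`` and split into ``k`` disjoint
    folds; each fold is predicted by a model fitted on the other k-1.  The
    same seed also seeds every fold's fit, so the whole procedure is
    reproducible.
    """
    if k < 2:
        raise ConfigurationError(f"k must be at least 2, got {k}")
    if k > dataset.n:
        raise ConfigurationError(f"k={k} exceeds the {dataset.n} available recordings")

    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    y_true = dataset.labels
    y_pred = np.empty_like(y_true)
    per_fold: list[dict] = []
    for fold_i, (train_idx, test_idx) in enumerate(splitter.split(dataset.features)):
        train = RegressionDataset(
            features=dataset.features[train_idx],
            labels=y_true[train_idx],
            metadata=dataset.metadata,
        )
        model = fit(train, method=method, hyperparameters=hyperparameters, seed=seed)
        fold_pred = np.atleast_1d(model.predict(dataset.features[test_idx]))
        y_pred[test_idx] = fold_pred
        fold_y = y_true[test_idx]
        fold_r2 = float("nan")
        if len(fold_y) >= 2 and np.ptp(fold_y) > 0:
            fold_r2 = r_squared(fold_y, fold_pred)
        per_fold.append(
            {
                "fold": fold_i,
                "n": int(len(fold_y)),
                "r_squared": fold_r2,
                "mse": mse(fold_y, fold_pred),
                "rmse": rmse(fold_y, fold_pred),
                "mae": mae(fold_y, fold_pred),
            }
        )

    fold_mean = {}
    for key in ("r_squared", "mse", "rmse", "mae"):
        finite = [f[key] for f in per_fold if np.isfinite(f[key])]
        fold_mean[key] = float(np.mean(finite)) if finite else float("nan")
    return EvaluationReport(
        method=method,
        n=dataset.n,
        k=k,
        fold_seed=seed,
        r_squared=r_squared(y_true, y_pred),
        mse=mse(y_true, y_pred),
        rmse=rmse(y_true, y_pred),
        mae=mae(y_true, y_pred),
        per_fold=per_fold,
        fold_mean=fold_mean,
        y_true=y_true.copy(),
        y_pred=y_pred,
        y_mean=float(y_true.mean()),
        ss_res=float(np.sum((y_true - y_pred) ** 2)),
        ss_total=float(np.sum((y_true - y_true.mean()) ** 2)),
    )


def evaluate_all(
    dataset: RegressionDataset,
    k: int = 10,
    seed: int = 0,
    methods: tuple[str, ...] | None = None,
) -> dict[str, EvaluationReport]:
    """Cross-validate every regressor on the same folds; keyed by method."""
    from .regress import METHODS

    out: dict[str, EvaluationReport] = {}
    for method in methods or METHODS:
        out[method] = cross_validate(dataset, method=method, k=k, seed=seed)
    return out
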