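"""Breath-volume regression with tree ensembles.

The feature vector is the respiration signal itself: detrended and linearly
resampled to a fixed length N (default 180 = 9 Hz x 20 s), so recordings of
any duration map onto the same feature space.  Four tree-based regressors are
supported — a single decision tree, random forest, gradient boosting (squared
-error loss) and AdaBoost — each predicting a scalar breath volume in litres.

The random-forest prediction is the plain average of its M member trees,
V = (1/M) * sum_i V_i, and the package exposes the member predictions so that
identity can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeRegressor

from .errors import ConfigurationError, InsufficientDataError
from .signal import RespirationSignal, detrend

__all__ = [
    "RegressionDataset",
    "TrainedVolumeModel",
    "build_features",
    "fit",
    "predict",
    "METHODS",
    "DEFAULT_N_FEATURES",
]

#: Canonical regressor names.
METHODS = ("decision_tree", "random_forest", "gradient_boosting", "adaboost")

#: Default feature-vector length: one 20 s recording at 9 frames/s.
DEFAULT_N_FEATURES = 180

#: Default ensemble size (trees) for the three ensemble methods.
DEFAULT_N_TREES = 100

_ENSEMBLES = frozenset({"random_forest", "gradient_boosting", "adaboost"})


@dataclass
class RegressionDataset:
    """Feature matrix of resampled signals paired with measured volumes."""

    features: np.ndarray  # (n, N), detrended resampled temperatures, deg C
    labels: np.ndarray  # (n,), measured volumes, litres
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels, dtype=float).ravel()
        if self.features.shape[0] != self.labels.shape[0]:
            raise ConfigurationError(
                f"{self.features.shape[0]} feature rows but {self.labels.shape[0]} labels"
            )
        if self.features.shape[0] < 1:
            raise InsufficientDataError("dataset must contain at least one recording")
        if not np.all(np.isfinite(self.features)):
            raise ConfigurationError("features contain non-finite values")
        if not np.all(np.isfinite(self.labels)) or np.any(self.labels <= 0):
            raise ConfigurationError("labels must be positive, finite volumes in litres")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class TrainedVolumeModel:
    """A fitted volume regressor plus the metadata needed to reuse it."""

    method: str
    estimator: Any  # fitted scikit-learn regressor (opaque)
    feature_length: int
    hyperparameters: dict
    seed: int

    def predict(self, features: np.ndarray) -> np.ndarray | float:
        return predict(self, features)

    def member_predictions(self, features: np.ndarray) -> np.ndarray:
        """Per-tree predictions of a random forest, shape (M, n_queries).

        Only defined for ``random_forest``; averaging this array along axis 0
        reproduces the ensemble output exactly.
        """
        if self.method != "random_forest":
            raise ConfigurationError(
                f"member_predictions is defined for random_forest, not {self.method}"
            )
        x = np.atleast_2d(np.asarray(features, dtype=float))
        return np.stack([tree.predict(x) for tree in self.estimator.estimators_])


def build_features(sig: RespirationSignal, n_features: int = DEFAULT_N_FEATURES) -> np.ndarray:
    """Turn a respiration signal into a fixed-length feature vector.

    Detrends (removing the camera's absolute-temperature bias and drift) and
    resamples to exactly ``n_features`` points by linear interpolation on the
    normalized time axis.  Deterministic.
    """
    if len(sig) == 0:
        raise InsufficientDataError("cannot build features from an empty signal")
    if n_features < 2:
        raise ConfigurationError(f"n_features must be at least 2, got {n_features}")
    if len(sig) == 1:
        raise InsufficientDataError("cannot detrend a single-sample signal")
    values = detrend(sig).values
    src = np.linspace(0.0, 1.0, len(values))
    dst = np.linspace(0.0, 1.0, n_features)
    return np.interp(dst, src, values)


def _make_estimator(method: str, hyperparameters: dict, seed: int):
    params = dict(hyperparameters)
    if method == "decision_tree":
        return DecisionTreeRegressor(random_state=seed, **params)
    params.setdefault("n_estimators", DEFAULT_N_TREES)
    if method == "random_forest":
        return RandomForestRegressor(random_state=seed, **params)
    if method == "gradient_boosting":
        # squared-error loss: the ensemble's gradients follow the MSE criterion
        params.setdefault("loss", "squared_error")
        return GradientBoostingRegressor(random_state=seed, **params)
    if method == "adaboost":
        return AdaBoostRegressor(random_state=seed, **params)
    raise ConfigurationError(f"unknown method {method!r}; expected one of {METHODS}")


def fit(
    dataset: RegressionDataset,
    method: str = "decision_tree",
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> TrainedVolumeModel:
    """Fit one of the four tree-based volume regressors.

    Identical seeds give identical models.  Ensembles need at least two
    training recordings; a lone decision tree accepts one.
    """
    hyperparameters = dict(hyperparameters or {})
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}; expected one of {METHODS}")
    if method in _ENSEMBLES and dataset.n < 2:
        raise InsufficientDataError(
            f"{method} needs at least 2 recordings, got {dataset.n}"
        )
    estimator = _make_estimator(method, hyperparameters, seed)
    estimator.fit(dataset.features, dataset.labels)
    return TrainedVolumeModel(
        method=method,
        estimator=estimator,
        feature_length=dataset.n_features,
        hyperparameters=hyperparameters,
        seed=seed,
    )


def predict(model: TrainedVolumeModel, features: np.ndarray) -> np.ndarray | float:
    """Predict breath volume (litres) for one feature vector or a batch.

    A 1-D input returns a scalar; a 2-D input returns one volume per row.
    """
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.feature_length:
        raise ConfigurationError(
            f"feature length {x.shape[1]} does not match model's {model.feature_length}"
        )
    out = model.estimator.predict(x)
    return float(out[0]) if single else out
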