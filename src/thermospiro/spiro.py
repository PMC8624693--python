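"""Clinical spirometry quantities: tidal volume, FVC, FEV1 and FEV1/FVC.

Volumes come either from a trained regression model applied to a respiration
signal, or from a directly supplied cumulative volume-time trace of a forced
manoeuvre.  For model-driven forced manoeuvres, the cumulative trace is
assembled by evaluating the model on growing prefixes of the signal.

Classification of the FEV1/FVC ratio follows the American Thoracic Society
thresholds: >= 0.70 is normal for adults, >= 0.85 for children aged 5-18.
A low ratio indicates airway obstruction; a ratio near 1 is flagged for
review of a restrictive condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InsufficientSignalError,
    ManoeuvreError,
)
from .rate import single_breath_window
from .regress import TrainedVolumeModel, build_features
from .signal import RespirationSignal

__all__ = [
    "VolumeTrace",
    "SpirometryReport",
    "tidal_volume",
    "predict_volume_trace",
    "fvc",
    "fev1",
    "classify_ratio",
    "RATIO_THRESHOLDS",
    "DEFAULT_ONSET_FRACTION",
    "DEFAULT_RESTRICTIVE_THRESHOLD",
]

#: Minimum normal FEV1/FVC by subject class (American Thoracic Society).
RATIO_THRESHOLDS = {"adult": 0.70, "child": 0.85}

#: Exhalation onset: first crossing of this fraction of the trace maximum.
DEFAULT_ONSET_FRACTION = 0.02

#: FEV1/FVC at or above this value is flagged for restrictive review.
DEFAULT_RESTRICTIVE_THRESHOLD = 0.95


@dataclass
class VolumeTrace:
    """Cumulative exhaled volume (litres) versus time during a manoeuvre."""

    volumes: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float).ravel()
        if self.frame_rate <= 0:
            raise ConfigurationError(f"frame_rate must be positive, got {self.frame_rate}")
        if len(self.volumes) == 0:
            raise InsufficientDataError("volume trace is empty")
        if np.any(self.volumes < 0):
            raise ManoeuvreError("volume trace contains negative volumes")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.volumes)) / self.frame_rate

    @property
    def duration(self) -> float:
        """Time spanned by the trace in seconds (last minus first sample)."""
        return (len(self.volumes) - 1) / self.frame_rate


@dataclass
class SpirometryReport:
    fvc: float  # litres
    fev1: float  # litres
    ratio: float  # FEV1/FVC, dimensionless in [0, 1]
    subject_class: str  # "adult" | "child"
    ratio_status: str  # "normal" | "low" | "high-restrictive-flag"
    tidal_volume: float | None = None  # litres, when measured


def tidal_volume(model: TrainedVolumeModel, sig: RespirationSignal) -> float:
    """Predict the volume of one normal relaxed breath.

    Slices the first complete peak-to-peak breath window out of the signal,
    builds the model's feature vector from that window alone, and returns the
    predicted volume.  The model must have been trained on single-breath
    windows for the representation to match.
    """
    window = single_breath_window(sig)
    features = build_features(window, model.feature_length)
    return float(model.predict(features))


def predict_volume_trace(
    model: TrainedVolumeModel,
    sig: RespirationSignal,
    min_prefix: int = 3,
) -> VolumeTrace:
    """Cumulative volume-time trace via model evaluation on signal prefixes.

    For each prefix ``sig[:t]`` (t >= min_prefix) the prefix is resampled to
    the model's feature length and the predicted volume becomes the trace
    value at time t.  The first ``min_prefix - 1`` samples repeat the first
    prediction so the trace keeps the signal's time base.
    """
    if len(sig) < min_prefix:
        raise InsufficientDataError(
            f"signal has {len(sig)} samples; need at least {min_prefix}"
        )
    preds = np.empty(len(sig), dtype=float)
    for t in range(min_prefix, len(sig) + 1):
        prefix = RespirationSignal(
            values=sig.values[:t], frame_rate=sig.frame_rate, roi=sig.roi
        )
        preds[t - 1] = float(model.predict(build_features(prefix, model.feature_length)))
    preds[: min_prefix - 1] = preds[min_prefix - 1]
    return VolumeTrace(volumes=np.clip(preds, 0.0, None), frame_rate=sig.frame_rate)


def fvc(trace: VolumeTrace, tolerance: float = 1e-6) -> float:
    """Forced vital capacity: the final (maximal) value of the volume trace.

    The trace must be non-decreasing up to ``tolerance`` litres of numerical
    wiggle; a genuinely decreasing trace indicates a failed manoeuvre.
    """
    if np.any(np.diff(trace.volumes) < -tolerance):
        raise ManoeuvreError(
            "volume trace decreases; the forced-exhalation manoeuvre is invalid"
        )
    return float(trace.volumes[-1])


def fev1(trace: VolumeTrace, onset_fraction: float = DEFAULT_ONSET_FRACTION) -> float:
    """Volume exhaled in the first second of the forced manoeuvre.

    The exhalation onset is where the cumulative volume crosses
    ``onset_fraction`` of the trace maximum (linearly interpolated between
    samples, so onset resolution is not limited to the frame period);
    FEV1 is the trace value at onset + 1 s, again linearly interpolated.
    Times past the end of the trace clamp to the final volume, which a
    non-decreasing trace can never exceed.
    """
    if trace.duration < 1.0:
        raise InsufficientDataError(
            f"trace spans {trace.duration:.3f} s; FEV1 needs at least 1 s"
        )
    volumes, times = trace.volumes, trace.times
    v_max = float(volumes.max())
    if v_max <= 0:
        raise InsufficientSignalError("volume trace never rises above zero")
    threshold = onset_fraction * v_max
    above = np.nonzero(volumes > threshold)[0]
    if len(above) == 0:
        raise InsufficientSignalError("volume trace never crosses the onset threshold")
    i = int(above[0])
    if i == 0:
        onset = 0.0
    else:
        dv = volumes[i] - volumes[i - 1]
        frac = (threshold - volumes[i - 1]) / dv if dv > 0 else 1.0
        onset = times[i - 1] + frac * (times[i] - times[i - 1])
    return float(np.interp(onset + 1.0, times, volumes))


def classify_ratio(
    fev1_l: float,
    fvc_l: float,
    subject_class: str = "adult",
    restrictive_threshold: float = DEFAULT_RESTRICTIVE_THRESHOLD,
    tolerance: float = 1e-6,
) -> SpirometryReport:
    """Compute FEV1/FVC and classify it for the given subject class.

    ``low`` (below the class threshold) suggests airway obstruction;
    ``high-restrictive-flag`` (ratio >= restrictive_threshold) marks the
    trace for review of a restrictive condition; otherwise ``normal``.
    """
    if subject_class not in RATIO_THRESHOLDS:
        raise ConfigurationError(
            f"subject_class must be one of {sorted(RATIO_THRESHOLDS)}, got {subject_class!r}"
        )
    if fvc_l <= 0:
        raise ConfigurationError(f"FVC must be positive, got {fvc_l}")
    if fev1_l < -tolerance or fev1_l > fvc_l + tolerance:
        raise ConfigurationError(
            f"FEV1 ({fev1_l}) must lie between 0 and FVC ({fvc_l})"
        )
    ratio = float(np.clip(fev1_l / fvc_l, 0.0, 1.0))
    if ratio >= restrictive_threshold:
        status = "high-restrictive-flag"
    elif ratio >= RATIO_THRESHOLDS[subject_class]:
        status = "normal"
    else:
        status = "low"
    return SpirometryReport(
        fvc=float(fvc_l),
        fev1=float(fev1_l),
        ratio=ratio,
        subject_class=subject_class,
        ratio_status=status,
    )
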