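"""Thermal-stack containers, ROI localization and respiration-signal extraction.

The respiration signal is the arithmetic mean temperature of a fixed nose/mouth
region of interest (ROI), frame by frame.  Exhaled air warms the region and
inhaled air cools it, so the mean-ROI trace oscillates at the breathing
frequency.  The ROI is localized once per recording and held fixed.

Pixel coordinates are 0-based; boxes are half-open on the right and bottom
(``x0 <= x < x1``, ``y0 <= y < y1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, InsufficientDataError, InsufficientSignalError

__all__ = [
    "RegionOfInterest",
    "ThermalSequence",
    "RespirationSignal",
    "locate_roi",
    "extract_signal",
    "detrend",
]

#: Default ROI box size (width, height) in pixels for automatic localization.
DEFAULT_BOX_SIZE = (16, 12)


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular pixel region, half-open: ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ConfigurationError(
                f"invalid ROI box ({self.x0},{self.y0})-({self.x1},{self.y1}): "
                "require 0 <= x0 < x1 and 0 <= y0 < y1"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) centre of the box in pixel coordinates."""
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def inside(self, width: int, height: int) -> bool:
        """True if the box lies fully inside a ``width x height`` frame."""
        return self.x1 <= width and self.y1 <= height

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.x0, self.y0, self.x1, self.y1)


def _as_roi(box: "RegionOfInterest | tuple[int, int, int, int]") -> RegionOfInterest:
    if isinstance(box, RegionOfInterest):
        return box
    return RegionOfInterest(*box)


@dataclass
class ThermalSequence:
    """Time-ordered stack of temperature rasters in degrees Celsius.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``.
    frame_rate
        Acquisition rate in frames per second.
    """

    frames: np.ndarray
    frame_rate: float = 9.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ConfigurationError(
                f"frames must be a 3-D (n, height, width) stack, got ndim={self.frames.ndim}"
            )
        if self.frame_rate <= 0:
            raise ConfigurationError(f"frame_rate must be positive, got {self.frame_rate}")
        if not np.all(np.isfinite(self.frames)):
            raise ConfigurationError("frames contain non-finite temperatures")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def timestamps(self) -> np.ndarray:
        """Uniform acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class RespirationSignal:
    """Mean-ROI temperature versus time — the pipeline's central 1-D object."""

    values: np.ndarray
    frame_rate: float
    roi: RegionOfInterest | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.frame_rate <= 0:
            raise ConfigurationError(f"frame_rate must be positive, got {self.frame_rate}")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("signal contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n samples at frame_rate)."""
        return len(self.values) / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate


def _box_mean_traces(frames: np.ndarray, box_w: int, box_h: int) -> np.ndarray:
    """Mean over every ``box_h x box_w`` window, per frame, via integral images.

    Returns an array of shape ``(n, H - box_h + 1, W - box_w + 1)`` where entry
    ``[t, y0, x0]`` is the box mean with top-left corner (x0, y0) at frame t.
    """
    n, h, w = frames.shape
    ii = np.zeros((n, h + 1, w + 1), dtype=float)
    ii[:, 1:, 1:] = frames.cumsum(axis=1).cumsum(axis=2)
    sums = (
        ii[:, box_h:, box_w:]
        - ii[:, box_h:, :-box_w]
        - ii[:, :-box_h, box_w:]
        + ii[:, :-box_h, :-box_w]
    )
    return sums / (box_w * box_h)


def locate_roi(
    seq: ThermalSequence,
    window: int | None = None,
    box_size: tuple[int, int] = DEFAULT_BOX_SIZE,
) -> RegionOfInterest:
    """Localize the breathing region as the box of maximal temporal variance.

    Scans every position of a fixed-size box and returns the one whose
    box-mean temperature has the largest variance over the first ``window``
    frames.  Breath modulation dominates the temporal variance wherever air
    flows over the skin, so this recovers the nose/mouth region without a
    visible-light face detector.  Ties are broken toward the smallest
    ``(y0, x0)``; the result is deterministic for a given stack.

    Parameters
    ----------
    seq
        Thermal stack to scan.
    window
        Number of leading frames to use; defaults to the whole stack.
        Must cover at least two seconds of recording.
    box_size
        ``(width, height)`` of the scanned box in pixels.

    Raises
    ------
    InsufficientDataError
        If the stack is shorter than ``window`` or the window is under 2 s.
    InsufficientSignalError
        If the temporal variance is zero everywhere (constant stack).
    """
    if window is None:
        window = seq.n_frames
    if window < 2 * seq.frame_rate:
        raise InsufficientDataError(
            f"window of {window} frames covers under 2 s at {seq.frame_rate} fps"
        )
    if seq.n_frames < window:
        raise InsufficientDataError(
            f"stack has {seq.n_frames} frames, fewer than window={window}"
        )
    box_w, box_h = box_size
    if box_w > seq.width or box_h > seq.height:
        raise ConfigurationError(
            f"box {box_w}x{box_h} exceeds frame size {seq.width}x{seq.height}"
        )
    traces = _box_mean_traces(seq.frames[:window], box_w, box_h)
    variance = traces.var(axis=0)
    if variance.max() <= 0.0:
        raise InsufficientSignalError(
            "temporal variance is zero everywhere; no breathing signal to localize"
        )
    # argmax on the C-ordered flat array picks the smallest (y0, x0) among ties
    y0, x0 = np.unravel_index(int(np.argmax(variance)), variance.shape)
    return RegionOfInterest(int(x0), int(y0), int(x0) + box_w, int(y0) + box_h)


def extract_signal(seq: ThermalSequence, roi: RegionOfInterest) -> RespirationSignal:
    """Average the ROI pixels of every frame into a respiration signal.

    ``values[t]`` is the arithmetic mean of the pixels inside ``roi`` at frame
    ``t``.  Averaging over the region suppresses per-pixel camera noise by the
    square root of the pixel count.
    """
    roi = _as_roi(roi)
    if not roi.inside(seq.width, seq.height):
        raise ConfigurationError(
            f"ROI {roi.as_tuple()} lies outside the {seq.width}x{seq.height} frame"
        )
    values = seq.frames[:, roi.y0 : roi.y1, roi.x0 : roi.x1].mean(axis=(1, 2))
    return RespirationSignal(
        values=values,
        frame_rate=seq.frame_rate,
        roi=roi,
        provenance=f"mean of ROI {roi.as_tuple()}",
    )


def detrend(sig: RespirationSignal) -> RespirationSignal:
    """Remove the least-squares linear trend (slope and offset).

    The camera reports absolute temperatures with a large calibration bias and
    slow drift; only the *change* in temperature carries breathing
    information, so the straight-line component is discarded.  The output has
    (numerically) zero mean.
    """
    if len(sig) < 2:
        raise InsufficientDataError("detrending requires at least 2 samples")
    t = sig.times
    slope, intercept = np.polyfit(t, sig.values, 1)
    residual = sig.values - (slope * t + intercept)
    out = replace(sig, values=residual)
    out.provenance = (sig.provenance + "; detrended").lstrip("; ")
    return out
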