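"""Respiration-rate estimation by peak counting.

The rate is the number of local maxima (completed breath peaks) in the
respiration signal divided by the recording duration, in breaths per minute.
A rate between 15 and 24 breaths/min (inclusive) is classified as normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientDataError, InsufficientSignalError
from .signal import RespirationSignal

__all__ = [
    "RespirationRateResult",
    "detect_peaks",
    "respiration_rate",
    "single_breath_window",
    "NORMAL_RATE_RANGE_BPM",
    "NEONATAL_MAX_BPM",
]

#: Inclusive normal adult respiration-rate band, breaths per minute.
NORMAL_RATE_RANGE_BPM = (15.0, 24.0)

#: Fastest physiological breathing rate (neonates), breaths per minute.
#: No two genuine breath peaks can be closer than one such period, which
#: sets the default minimum peak separation.
NEONATAL_MAX_BPM = 55.0

#: Default peak prominence as a fraction of the signal's peak-to-trough range.
DEFAULT_PROMINENCE_FRACTION = 0.25


@dataclass
class RespirationRateResult:
    n_peaks: int
    duration: float  # seconds
    rate: float  # breaths per minute = n_peaks / duration * 60
    status: str  # "normal" | "abnormal"
    peak_indices: np.ndarray


def _resolve_prominence(values: np.ndarray, min_prominence: float | None) -> float:
    if min_prominence is not None:
        return float(min_prominence)
    return DEFAULT_PROMINENCE_FRACTION * float(np.ptp(values))


def detect_peaks(
    sig: RespirationSignal,
    min_prominence: float | None = None,
    min_separation: float = 60.0 / NEONATAL_MAX_BPM,
) -> np.ndarray:
    """Indices of breath peaks: prominent, well-separated local maxima.

    Parameters
    ----------
    min_prominence
        Minimum peak prominence in deg C.  Defaults to 25% of the signal's
        peak-to-trough range, which rejects camera-noise wiggles while
        keeping every genuine breath.
    min_separation
        Minimum spacing between peaks in seconds; defaults to one neonatal
        breath period (60/55 s).  The spacing is enforced in whole samples,
        rounded down, so the limiting rate itself is still admitted.

    Returns a strictly increasing index array; endpoints are never peaks.
    An empty array (no peaks, e.g. a monotone signal) is a valid result.
    """
    values = sig.values
    if len(values) < 3 or np.ptp(values) == 0.0:
        return np.array([], dtype=int)
    prominence = _resolve_prominence(values, min_prominence)
    distance = max(1, math.floor(min_separation * sig.frame_rate))
    peaks, _ = find_peaks(values, prominence=prominence or None, distance=distance)
    return peaks


def respiration_rate(
    sig: RespirationSignal,
    min_prominence: float | None = None,
    min_separation: float = 60.0 / NEONATAL_MAX_BPM,
) -> RespirationRateResult:
    """Count breath peaks and convert to breaths per minute.

    The count is of completed peaks; the rate ``n_peaks / duration * 60``
    is reported without rounding, so its resolution is one breath per
    recording duration (3 breaths/min for the default 20 s recording).
    """
    if len(sig) == 0 or sig.duration <= 0:
        raise InsufficientDataError("cannot estimate a rate from an empty signal")
    peaks = detect_peaks(sig, min_prominence=min_prominence, min_separation=min_separation)
    rate = len(peaks) / sig.duration * 60.0
    lo, hi = NORMAL_RATE_RANGE_BPM
    status = "normal" if lo <= rate <= hi else "abnormal"
    return RespirationRateResult(
        n_peaks=len(peaks),
        duration=sig.duration,
        rate=rate,
        status=status,
        peak_indices=peaks,
    )


def single_breath_window(
    sig: RespirationSignal,
    min_prominence: float | None = None,
    min_separation: float = 60.0 / NEONATAL_MAX_BPM,
) -> RespirationSignal:
    """Slice out the first complete peak-to-peak breath of a recording.

    Used for tidal-volume prediction, where the model consumes exactly one
    breath cycle.  Requires at least two detected peaks.
    """
    peaks = detect_peaks(sig, min_prominence=min_prominence, min_separation=min_separation)
    if len(peaks) < 2:
        raise InsufficientSignalError(
            f"need at least one complete peak-to-peak breath; found {len(peaks)} peak(s)"
        )
    out = replace(sig, values=sig.values[peaks[0] : peaks[1] + 1])
    out.provenance = (sig.provenance + "; first breath window").lstrip("; ")
    return out
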