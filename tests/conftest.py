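"""Shared fixtures: small, fast synthetic recordings with known ground truth."""

import numpy as np
import pytest

from thermospiro import RespirationSignal, SynthConfig

#: Reduced-size camera used by most unit tests; the ROI box keeps the
#: default 16x12 shape so automatic localization behaves as in full frames.
SMALL = dict(width=48, height=36, roi_box=(16, 12, 32, 24))


@pytest.fixture
def small_config():
    """Noiseless, drift-free small stack: 18 breaths/min, 20 s at 9 Hz."""
    return SynthConfig(noise_sd=0.0, drift_slope=0.0, **SMALL)


@pytest.fixture
def noisy_small_config():
    return SynthConfig(noise_sd=0.2, **SMALL)


def sinusoid_signal(
    rate_bpm: float = 18.0,
    duration: float = 20.0,
    frame_rate: float = 9.0,
    amplitude: float = 0.5,
    baseline: float = 34.0,
) -> RespirationSignal:
    """Directly constructed sinusoidal respiration signal (no frames)."""
    n = int(frame_rate * duration)
    t = np.arange(n) / frame_rate
    values = baseline + amplitude * np.sin(2 * np.pi * rate_bpm / 60.0 * t)
    return RespirationSignal(values=values, frame_rate=frame_rate)
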