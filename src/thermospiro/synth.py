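"""Synthetic thermal-video generator for the spirometry pipeline.

Emulates a low-resolution mobile thermal camera (160x120 pixels, 9 frames/s)
pointed at a face: a rectangular nose/mouth region whose mean temperature
oscillates with breathing, additive per-pixel Gaussian camera noise, and a
slow linear calibration drift shared by all pixels.  Ground truth (per-breath
volumes, breathing rate, planted ROI) is returned alongside every stack so
estimators can be tested by parameter recovery.

The breath-to-temperature forward model is deliberately simple and linear:
the ROI temperature deviation is ``breath_amplitude * volume_per_breath``
times a normalized periodic waveform.  Exhalation warms the region, so the
waveform's positive lobe is the exhale.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .signal import RegionOfInterest, ThermalSequence, extract_signal, locate_roi

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_sequence",
    "generate_dataset",
    "breath_waveform_samples",
    "VOLUME_ENVELOPE_L",
]

#: Breath-volume range (litres) the regression stage is trained over; spans
#: shallow paediatric tidal breaths up to a deep adult forced exhalation.
VOLUME_ENVELOPE_L = (0.2, 3.5)

_WAVEFORMS = ("sinusoid", "asymmetric-exhale")


@dataclass
class SynthConfig:
    """Generator settings; defaults reproduce the reference camera and protocol.

    Attributes
    ----------
    frame_rate : float
        Acquisition rate, frames per second.
    duration : float
        Recording length, seconds.
    width, height : int
        Frame size in pixels.
    roi_box : RegionOfInterest or tuple
        Planted nose/mouth region (half-open pixel box).
    baseline_temp : float
        Mean skin temperature in the ROI, deg C.
    breath_amplitude : float
        Peak ROI temperature deviation per litre of breath, deg C / L.
    breath_rate : float
        Breathing rate, breaths per minute.
    breath_waveform : str
        ``"sinusoid"`` for relaxed tidal breathing, ``"asymmetric-exhale"``
        (fast rise, slow decay) for forced-expiration manoeuvres.
    noise_sd : float
        Per-pixel, per-frame Gaussian camera noise, deg C.
    drift_slope : float
        Linear calibration drift shared by all pixels, deg C / s.
    volume_per_breath : float
        Air volume moved per breath, litres.
    seed : int
        Seed for the noise generator; identical seeds give identical stacks.
    """

    frame_rate: float = 9.0
    duration: float = 20.0
    width: int = 160
    height: int = 120
    roi_box: RegionOfInterest | tuple[int, int, int, int] = (72, 54, 88, 66)
    baseline_temp: float = 34.0
    breath_amplitude: float = 1.0
    breath_rate: float = 18.0
    breath_waveform: str = "sinusoid"
    noise_sd: float = 0.3
    drift_slope: float = 0.01
    volume_per_breath: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.roi_box, RegionOfInterest):
            self.roi_box = RegionOfInterest(*self.roi_box)
        self.validate()

    def validate(self) -> None:
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ConfigurationError("frame_rate and duration must be positive")
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("frame dimensions must be positive")
        if not self.roi_box.inside(self.width, self.height):
            raise ConfigurationError(
                f"roi_box {self.roi_box.as_tuple()} lies outside the "
                f"{self.width}x{self.height} frame"
            )
        if self.breath_rate <= 0 or self.volume_per_breath <= 0:
            raise ConfigurationError("breath_rate and volume_per_breath must be positive")
        if self.frame_rate <= 2 * self.breath_rate / 60.0:
            raise ConfigurationError(
                f"frame_rate {self.frame_rate} fps cannot sample "
                f"{self.breath_rate} breaths/min (Nyquist)"
            )
        if self.breath_waveform not in _WAVEFORMS:
            raise ConfigurationError(
                f"breath_waveform must be one of {_WAVEFORMS}, got {self.breath_waveform!r}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")

    @property
    def n_frames(self) -> int:
        """Frame count, rounded down; partial trailing breaths are allowed."""
        return int(math.floor(self.frame_rate * self.duration))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roi_box"] = self.roi_box.as_tuple()
        return d


@dataclass
class GroundTruth:
    """What the generator actually did — for parameter-recovery tests."""

    volume_trace: np.ndarray  # instantaneous lung-air volume, litres, >= 0
    per_breath_volumes: list[float]
    true_rate: float  # breaths/min
    roi_box: RegionOfInterest


def _normalized_waveform(phase: np.ndarray, kind: str) -> np.ndarray:
    """Periodic breath waveform with zero cycle-mean and peak magnitude 1.

    ``phase`` is in cycles (1.0 = one full breath).  The positive lobe is
    the exhale (warming).
    """
    if kind == "sinusoid":
        return np.sin(2 * np.pi * phase)
    # asymmetric-exhale: rapid raised-cosine rise over the first 20% of the
    # cycle, exponential relaxation afterwards - the shape of a forced blow.
    rise_frac, decay_tau = 0.2, 0.25

    def raw(p: np.ndarray) -> np.ndarray:
        p = np.mod(p, 1.0)
        out = np.where(
            p < rise_frac,
            0.5 * (1 - np.cos(np.pi * p / rise_frac)),
            np.exp(-(p - rise_frac) / decay_tau),
        )
        return out

    # centre and scale using a dense single-cycle reference grid so the
    # normalization is independent of the sampling instants
    ref = raw(np.linspace(0.0, 1.0, 2048, endpoint=False))
    centred_ref = ref - ref.mean()
    scale = np.abs(centred_ref).max()
    return (raw(phase) - ref.mean()) / scale


def breath_waveform_samples(config: SynthConfig) -> np.ndarray:
    """The normalized waveform at the configured sampling instants."""
    t = np.arange(config.n_frames) / config.frame_rate
    return _normalized_waveform(t * config.breath_rate / 60.0, config.breath_waveform)


def generate_sequence(config: SynthConfig) -> tuple[ThermalSequence, GroundTruth]:
    """Render one synthetic thermal recording plus its ground truth.

    Every pixel carries the baseline temperature, the shared linear drift and
    i.i.d. Gaussian camera noise; pixels inside ``roi_box`` additionally carry
    the breath oscillation with peak deviation
    ``breath_amplitude * volume_per_breath``.  Noise is applied per pixel
    *before* any ROI averaging, so downstream mean-ROI extraction genuinely
    earns its noise suppression.
    """
    config.validate()
    n = config.n_frames
    t = np.arange(n) / config.frame_rate
    w = _normalized_waveform(t * config.breath_rate / 60.0, config.breath_waveform)
    deviation = config.breath_amplitude * config.volume_per_breath * w

    frames = np.empty((n, config.height, config.width), dtype=float)
    frames[:] = config.baseline_temp + config.drift_slope * t[:, None, None]
    box = config.roi_box
    frames[:, box.y0 : box.y1, box.x0 : box.x1] += deviation[:, None, None]
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        frames += rng.normal(0.0, config.noise_sd, size=frames.shape)

    # instantaneous lung-air volume: waveform rescaled to [0, volume_per_breath]
    w_min, w_max = w.min(), w.max()
    span = (w_max - w_min) or 1.0
    volume_trace = config.volume_per_breath * (w - w_min) / span
    n_complete = int(math.floor(config.duration * config.breath_rate / 60.0))
    truth = GroundTruth(
        volume_trace=volume_trace,
        per_breath_volumes=[config.volume_per_breath] * n_complete,
        true_rate=config.breath_rate,
        roi_box=box,
    )
    return ThermalSequence(frames=frames, frame_rate=config.frame_rate), truth


def generate_dataset(
    n_recordings: int,
    volume_range: tuple[float, float] = VOLUME_ENVELOPE_L,
    config_template: SynthConfig | None = None,
    seed: int = 0,
    n_features: int = 180,
    window: str = "full",
    locate: bool = False,
):
    """Build a labelled regression dataset from synthetic recordings.

    Draws one breath volume per recording uniformly from ``volume_range``,
    renders the recording, extracts its respiration signal and resamples it
    into an ``n_features``-long feature vector; the drawn volume is the label.
    Stands in for a multi-subject corpus where each subject breathes a
    protocol-instructed rhythm and only the moved volume differs.

    Parameters
    ----------
    window
        ``"full"`` uses the whole recording; ``"breath"`` uses only the
        first complete peak-to-peak breath window (the representation used
        for tidal-volume prediction).
    locate
        If True, localize the ROI from the stack instead of using the
        planted box; slower, but exercises the full pipeline.

    Returns
    -------
    RegressionDataset
        Features, labels (litres) and metadata recording the seed and the
        generator configuration.
    """
    from .rate import single_breath_window
    from .regress import RegressionDataset, build_features

    if n_recordings < 1:
        raise ConfigurationError("n_recordings must be at least 1")
    lo, hi = float(volume_range[0]), float(volume_range[1])
    if not (0 < lo <= hi):
        raise ConfigurationError(f"invalid volume_range ({lo}, {hi})")
    if window not in ("full", "breath"):
        raise ConfigurationError(f"window must be 'full' or 'breath', got {window!r}")
    template = config_template if config_template is not None else SynthConfig()

    rng = np.random.default_rng(seed)
    volumes = rng.uniform(lo, hi, size=n_recordings)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_recordings)

    features = np.empty((n_recordings, n_features), dtype=float)
    for i in range(n_recordings):
        cfg = replace(
            template, volume_per_breath=float(volumes[i]), seed=int(child_seeds[i])
        )
        seq, truth = generate_sequence(cfg)
        roi = locate_roi(seq) if locate else truth.roi_box
        sig = extract_signal(seq, roi)
        if window == "breath":
            sig = single_breath_window(sig)
        features[i] = build_features(sig, n_features)

    metadata = {
        "seed": int(seed),
        "n_recordings": int(n_recordings),
        "volume_range": (lo, hi),
        "window": window,
        "located_roi": bool(locate),
        "config_template": template.to_dict(),
    }
    return RegressionDataset(features=features, labels=volumes, metadata=metadata)
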