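"""ROI localization, signal extraction and detrending."""

import numpy as np
import pytest
from dataclasses import replace

from thermospiro import (
    ConfigurationError,
    InsufficientDataError,
    InsufficientSignalError,
    RegionOfInterest,
    RespirationSignal,
    SynthConfig,
    ThermalSequence,
    detrend,
    extract_signal,
    generate_sequence,
    locate_roi,
)
from conftest import SMALL


def brute_force_locate(seq, box_w=16, box_h=12):
    """Exhaustive-position oracle: max temporal variance of box-mean."""
    best, best_pos = -1.0, None
    for y0 in range(seq.height - box_h + 1):
        for x0 in range(seq.width - box_w + 1):
            trace = seq.frames[:, y0 : y0 + box_h, x0 : x0 + box_w].mean(axis=(1, 2))
            v = trace.var()
            if v > best + 1e-15:  # strict improvement keeps smallest (y0, x0) on ties
                best, best_pos = v, (x0, y0)
    return RegionOfInterest(best_pos[0], best_pos[1], best_pos[0] + box_w, best_pos[1] + box_h)


class TestLocateRoi:
    def test_matches_exhaustive_oracle_on_small_stacks(self):
        """Integral-image scan equals the brute-force oracle position for position."""
        for seed in (0, 1, 2):
            cfg = SynthConfig(
                width=64, height=48, roi_box=(40, 20, 56, 32), noise_sd=0.25, seed=seed
            )
            seq, _ = generate_sequence(cfg)
            assert locate_roi(seq).as_tuple() == brute_force_locate(seq).as_tuple()

    def test_recovers_planted_roi_under_noise(self):
        cfg = SynthConfig(roi_box=(40, 60, 56, 72), noise_sd=0.1, seed=5)
        seq, truth = generate_sequence(cfg)
        found = locate_roi(seq)
        cx, cy = found.center
        tx, ty = truth.roi_box.center
        assert np.hypot(cx - tx, cy - ty) <= 4.0

    def test_noiseless_overlap_with_planted_box(self, small_config):
        seq, truth = generate_sequence(small_config)
        found = locate_roi(seq)
        ix = max(0, min(found.x1, truth.roi_box.x1) - max(found.x0, truth.roi_box.x0))
        iy = max(0, min(found.y1, truth.roi_box.y1) - max(found.y0, truth.roi_box.y0))
        inter = ix * iy
        union = found.width * found.height + truth.roi_box.width * truth.roi_box.height - inter
        assert inter / union >= 0.5

    def test_constant_stack_raises_insufficient_signal(self):
        seq = ThermalSequence(frames=np.full((40, 36, 48), 30.0), frame_rate=9.0)
        with pytest.raises(InsufficientSignalError):
            locate_roi(seq)

    def test_stack_shorter_than_window_raises(self, small_config):
        seq, _ = generate_sequence(small_config)
        with pytest.raises(InsufficientDataError):
            locate_roi(seq, window=seq.n_frames + 1)

    def test_deterministic_for_a_given_stack(self, noisy_small_config):
        seq, _ = generate_sequence(noisy_small_config)
        assert locate_roi(seq).as_tuple() == locate_roi(seq).as_tuple()


class TestExtractSignal:
    def test_single_pixel_roi_is_that_pixels_trace(self, noisy_small_config):
        seq, _ = generate_sequence(noisy_small_config)
        sig = extract_signal(seq, RegionOfInterest(3, 5, 4, 6))
        assert np.array_equal(sig.values, seq.frames[:, 5, 3])

    def test_constant_frames_give_constant_signal(self):
        seq = ThermalSequence(frames=np.full((20, 10, 12), 30.0), frame_rate=9.0)
        sig = extract_signal(seq, RegionOfInterest(0, 0, 12, 10))
        assert np.allclose(sig.values, 30.0)

    def test_noiseless_roundtrip_matches_closed_form(self, small_config):
        """Extracted ROI mean equals baseline + A*V*sin(2 pi f t) exactly."""
        seq, truth = generate_sequence(small_config)
        sig = extract_signal(seq, truth.roi_box)
        t = np.arange(seq.n_frames) / small_config.frame_rate
        expected = (
            small_config.baseline_temp
            + small_config.breath_amplitude
            * small_config.volume_per_breath
            * np.sin(2 * np.pi * small_config.breath_rate / 60.0 * t)
        )
        assert np.allclose(sig.values, expected, atol=1e-12)

    def test_out_of_bounds_roi_rejected(self, small_config):
        seq, _ = generate_sequence(small_config)
        with pytest.raises(ConfigurationError):
            extract_signal(seq, RegionOfInterest(40, 30, 60, 40))

    def test_linearity_in_the_stack(self, noisy_small_config):
        """signal(A + B) == signal(A) + signal(B)."""
        a, _ = generate_sequence(noisy_small_config)
        b, _ = generate_sequence(replace(noisy_small_config, seed=99))
        roi = RegionOfInterest(16, 12, 32, 24)
        summed = ThermalSequence(frames=a.frames + b.frames, frame_rate=9.0)
        lhs = extract_signal(summed, roi).values
        rhs = extract_signal(a, roi).values + extract_signal(b, roi).values
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestDetrend:
    def test_pure_ramp_becomes_zero(self):
        t = np.arange(90) / 9.0
        sig = RespirationSignal(values=5.0 + 0.3 * t, frame_rate=9.0)
        assert np.max(np.abs(detrend(sig).values)) <= 1e-9

    def test_sinusoid_plus_ramp_recovers_sinusoid(self):
        t = np.arange(180) / 9.0
        # whole cycles, even-symmetric about the grid midpoint: exactly
        # orthogonal to both the constant and the linear trend
        wave = 0.4 * np.cos(2 * np.pi * 0.3 * (t - t[-1] / 2))
        sig = RespirationSignal(values=wave + 2.0 + 0.05 * t, frame_rate=9.0)
        out = detrend(sig).values
        assert np.max(np.abs(out - wave)) <= 1e-6

    def test_zero_signal_stays_zero(self):
        sig = RespirationSignal(values=np.zeros(30), frame_rate=9.0)
        assert np.allclose(detrend(sig).values, 0.0)

    def test_output_mean_is_zero(self, noisy_small_config):
        seq, truth = generate_sequence(noisy_small_config)
        sig = extract_signal(seq, truth.roi_box)
        assert detrend(sig).values.mean() == pytest.approx(0.0, abs=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            detrend(RespirationSignal(values=[1.0], frame_rate=9.0))
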