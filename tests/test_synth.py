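"""Generator correctness: frame counts, determinism, spectral content, scaling."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.signal import periodogram

from thermospiro import (
    ConfigurationError,
    SynthConfig,
    breath_waveform_samples,
    extract_signal,
    generate_dataset,
    generate_sequence,
)
from conftest import SMALL


def roi_mean(seq, box):
    return seq.frames[:, box.y0 : box.y1, box.x0 : box.x1].mean(axis=(1, 2))


class TestGenerateSequence:
    def test_frame_count_and_cycles_noiseless(self, small_config):
        """18 breaths/min for 20 s at 9 Hz gives 180 frames and 6 full cycles."""
        seq, truth = generate_sequence(small_config)
        assert seq.n_frames == 180
        trace = roi_mean(seq, truth.roi_box)
        # exactly 6 cycles: the trace is periodic with period 30 frames
        assert np.allclose(trace[:150], trace[30:], atol=1e-12)
        assert len(truth.per_breath_volumes) == 6

    def test_identical_seeds_give_identical_stacks(self):
        cfg = SynthConfig(seed=7, **SMALL)
        a, _ = generate_sequence(cfg)
        b, _ = generate_sequence(SynthConfig(seed=7, **SMALL))
        assert np.array_equal(a.frames, b.frames)

    def test_different_seeds_differ(self):
        a, _ = generate_sequence(SynthConfig(seed=1, **SMALL))
        b, _ = generate_sequence(SynthConfig(seed=2, **SMALL))
        assert not np.array_equal(a.frames, b.frames)

    def test_dominant_spectral_peak_at_breath_frequency(self):
        """Periodogram oracle: 20 breaths/min -> dominant peak at 0.333 Hz."""
        cfg = SynthConfig(noise_sd=0.3, breath_rate=20.0, **SMALL)
        seq, truth = generate_sequence(cfg)
        trace = roi_mean(seq, truth.roi_box)
        freqs, power = periodogram(trace - trace.mean(), fs=cfg.frame_rate)
        assert freqs[np.argmax(power)] == pytest.approx(20.0 / 60.0, abs=0.02)

    def test_noiseless_trace_exactly_periodic(self, small_config):
        """Autocorrelation at one breath period is essentially 1."""
        seq, truth = generate_sequence(small_config)
        x = roi_mean(seq, truth.roi_box)
        x = x - x.mean()
        lag = int(small_config.frame_rate * 60 / small_config.breath_rate)
        r = np.dot(x[:-lag], x[lag:]) / np.sqrt(np.dot(x[:-lag], x[:-lag]) * np.dot(x[lag:], x[lag:]))
        assert r >= 0.999

    def test_outside_roi_carries_no_breath_component(self):
        """Spectral power at the breath frequency outside the ROI is noise-floor."""
        cfg = SynthConfig(noise_sd=0.2, drift_slope=0.0, **SMALL)
        seq, truth = generate_sequence(cfg)
        box = truth.roi_box
        outside = seq.frames[:, : box.y0, : box.x0].mean(axis=(1, 2))
        freqs, power = periodogram(outside - outside.mean(), fs=cfg.frame_rate)
        f_breath = cfg.breath_rate / 60.0
        p_breath = power[np.argmin(np.abs(freqs - f_breath))]
        assert p_breath <= 10 * np.median(power)

    def test_amplitude_scales_linearly_with_volume(self):
        """Doubling volume_per_breath doubles the noiseless peak-to-trough range."""
        base = SynthConfig(noise_sd=0.0, drift_slope=0.0, volume_per_breath=0.8, **SMALL)
        doubled = replace(base, volume_per_breath=1.6)
        a = roi_mean(*_seq_and_box(base))
        b = roi_mean(*_seq_and_box(doubled))
        assert np.ptp(b) == pytest.approx(2 * np.ptp(a), rel=1e-12)

    def test_asymmetric_waveform_rises_faster_than_it_decays(self):
        cfg = SynthConfig(
            noise_sd=0.0, drift_slope=0.0, breath_waveform="asymmetric-exhale", **SMALL
        )
        w = breath_waveform_samples(cfg)
        peak = int(np.argmax(w[:30]))  # within the first cycle (30 frames)
        assert peak < 15  # rise occupies the early part of the cycle
        assert abs(w.max()) == pytest.approx(1.0, abs=1e-3)

    def test_peak_deviation_equals_amplitude_times_volume(self, small_config):
        # 13.5 breaths/min at 9 Hz puts a sample exactly on the waveform peak
        cfg = replace(small_config, breath_rate=13.5)
        seq, truth = generate_sequence(cfg)
        trace = roi_mean(seq, truth.roi_box)
        expected = cfg.breath_amplitude * cfg.volume_per_breath
        assert trace.max() - cfg.baseline_temp == pytest.approx(expected, rel=1e-6)

    def test_ground_truth_rate_matches_config(self, small_config):
        _, truth = generate_sequence(small_config)
        assert truth.true_rate == small_config.breath_rate
        assert np.all(truth.volume_trace >= 0)
        assert truth.volume_trace.max() == pytest.approx(small_config.volume_per_breath)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(frame_rate=0.0),
            dict(duration=-1.0),
            dict(width=0),
            dict(roi_box=(40, 30, 60, 40)),  # outside 48x36 frame
            dict(breath_rate=300.0),  # violates Nyquist at 9 fps
            dict(breath_waveform="square"),
            dict(noise_sd=-0.1),
            dict(volume_per_breath=0.0),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        kwargs = {**SMALL, **bad}
        with pytest.raises(ConfigurationError):
            SynthConfig(**kwargs)


def _seq_and_box(cfg):
    seq, truth = generate_sequence(cfg)
    return seq, truth.roi_box


class TestGenerateDataset:
    def test_labels_within_requested_range(self, noisy_small_config):
        ds = generate_dataset(10, (0.2, 3.5), noisy_small_config, seed=11, n_features=60)
        assert ds.n == 10
        assert np.all((ds.labels >= 0.2) & (ds.labels <= 3.5))
        assert ds.features.shape == (10, 60)

    def test_degenerate_volume_interval(self, noisy_small_config):
        ds = generate_dataset(1, (1.0, 1.0), noisy_small_config, seed=0, n_features=60)
        assert ds.labels[0] == 1.0

    def test_same_seed_reproduces_features(self, noisy_small_config):
        a = generate_dataset(4, (0.5, 2.0), noisy_small_config, seed=3, n_features=60)
        b = generate_dataset(4, (0.5, 2.0), noisy_small_config, seed=3, n_features=60)
        assert np.array_equal(a.features, b.features)
        assert np.array_equal(a.labels, b.labels)
        assert a.metadata["seed"] == 3

    def test_empty_or_invalid_range_rejected(self, noisy_small_config):
        with pytest.raises(ConfigurationError):
            generate_dataset(3, (2.0, 1.0), noisy_small_config)
        with pytest.raises(ConfigurationError):
            generate_dataset(0, (0.2, 3.5), noisy_small_config)

    def test_breath_window_mode_yields_single_cycle_features(self, small_config):
        ds = generate_dataset(
            2, (0.5, 2.0), small_config, seed=1, n_features=60, window="breath"
        )
        # one peak-to-peak cycle: interior minimum, endpoints near the maxima
        row = ds.features[0]
        assert row.argmin() not in (0, len(row) - 1)
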