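"""Pre-processing chain: filters, artifacts, segmentation, quality control."""

import numpy as np
import pytest
from scipy import signal as sps

from conftest import make_tensor
from pepato.errors import (
    DegenerateCycleError,
    InsufficientCyclesError,
    ParameterError,
)
from pepato.io_eurobench import EmgRecording, GaitEvents, PipelineConfig
from pepato.preprocessing import (
    apply_notch,
    apply_quality_gate,
    bandpass_filter,
    detect_outlier_cycles,
    detect_spectral_artifacts,
    detect_touchdown_from_heel,
    normalize_amplitude,
    rectify_and_envelope,
    segment_and_normalize,
)

RATE = 2000.0


def sine(freq, duration=4.0, rate=RATE, amplitude=1.0):
    t = np.arange(int(duration * rate)) / rate
    return amplitude * np.sin(2 * np.pi * freq * t)


def band_rms(x, freq, rate=RATE, half_bw=2.0):
    f, pxx = sps.periodogram(x, fs=rate)
    mask = np.abs(f - freq) <= half_bw
    return np.sqrt(np.trapezoid(pxx[mask], f[mask]))


class TestBandpass:
    def test_stopband_attenuates_slow_drift(self):
        x = sine(5.0)
        y = bandpass_filter(x, RATE)
        assert np.sqrt(np.mean(y**2)) <= 0.1 * np.sqrt(np.mean(x**2))

    def test_passband_is_transparent(self):
        x = sine(100.0)
        y = bandpass_filter(x, RATE)
        core = slice(2000, -2000)  # ignore filter edge transients
        assert np.sqrt(np.mean(y[core] ** 2)) == pytest.approx(
            np.sqrt(np.mean(x[core] ** 2)), rel=0.05
        )

    def test_zero_phase_pulse_not_shifted(self):
        x = np.zeros(4000)
        x[2000] = 1.0
        y = bandpass_filter(x, RATE)
        lag = np.argmax(np.correlate(y, x, mode="full")) - (len(x) - 1)
        assert lag == 0

    def test_invalid_band_edges(self):
        with pytest.raises(ParameterError):
            bandpass_filter(sine(100), RATE, low=30.0, high=1500.0)


class TestNotch:
    def test_target_killed_neighbors_kept(self):
        x = sine(155.0) + sine(100.0)
        y = apply_notch(x, RATE, 155.0, q=30.0)
        core = slice(2000, -2000)
        drop_db = 20 * np.log10(
            band_rms(x[core], 155.0) / max(band_rms(y[core], 155.0), 1e-30)
        )
        assert drop_db >= 30.0
        assert band_rms(y[core], 100.0) == pytest.approx(
            band_rms(x[core], 100.0), rel=0.05
        )

    def test_mains_50hz_removed(self):
        x = sine(50.0, amplitude=0.3) + sine(120.0)
        y = apply_notch(x, RATE, 50.0)
        core = slice(2000, -2000)
        assert band_rms(y[core], 50.0) < 0.03 * band_rms(x[core], 50.0)

    def test_zero_signal_stays_zero(self):
        assert np.allclose(apply_notch(np.zeros(1000), RATE, 155.0), 0.0)

    def test_frequency_out_of_range(self):
        with pytest.raises(ParameterError):
            apply_notch(np.zeros(1000), RATE, 1200.0)


class TestSpectralArtifacts:
    @staticmethod
    def recording(line_freq=None, n_line_channels=8, seed=0):
        rng = np.random.default_rng(seed)
        n = int(6 * RATE)
        x = rng.standard_normal((n, 8))
        x = bandpass_filter(x, RATE, 30.0, 400.0)
        if line_freq is not None:
            t = np.arange(n) / RATE
            line = 2.0 * np.sin(2 * np.pi * line_freq * t)
            x[:, :n_line_channels] += line[:, None]
        names = [f"R_ch{i}" for i in range(8)]
        return EmgRecording(RATE, names, x)

    def test_shared_155hz_peak_detected(self):
        freqs = detect_spectral_artifacts(self.recording(line_freq=155.0))
        assert any(abs(f - 155.0) <= 2.0 for f in freqs)

    def test_clean_noise_yields_nothing(self):
        assert detect_spectral_artifacts(self.recording()) == []

    def test_single_channel_peak_not_shared(self):
        freqs = detect_spectral_artifacts(
            self.recording(line_freq=155.0, n_line_channels=1)
        )
        assert freqs == []


class TestEnvelope:
    def test_constant_passes_through(self):
        env = rectify_and_envelope(np.full(4000, -2.5), RATE)
        assert np.allclose(env[1000:-1000], 2.5, rtol=0.01)

    def test_sine_plateau_is_mean_absolute_value(self):
        # mean of |a sin| over a period is 2a/pi
        env = rectify_and_envelope(sine(100.0, amplitude=3.0), RATE)
        assert np.median(env[2000:-2000]) == pytest.approx(2 * 3.0 / np.pi, rel=0.05)

    def test_non_negative_everywhere(self):
        rng = np.random.default_rng(3)
        env = rectify_and_envelope(rng.standard_normal(5000), RATE)
        assert env.min() >= 0.0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            rectify_and_envelope(np.zeros(100), RATE, cutoff=1500.0)


class TestSegmentation:
    def test_phase_dimension_is_exactly_n_phase(self):
        rng = np.random.default_rng(0)
        env = np.abs(rng.standard_normal((int(15 * RATE), 3)))
        events = GaitEvents(np.cumsum(rng.uniform(0.9, 1.3, 11)))
        tensor = segment_and_normalize(env, events, RATE, 200)
        assert tensor.envelopes_mV.shape == (10, 200, 3)
        assert tensor.cycle_durations == pytest.approx(np.diff(events.touchdown_times))

    def test_constant_envelope_stays_constant(self):
        env = np.ones((int(3 * RATE), 2))
        tensor = segment_and_normalize(env, GaitEvents([0.5, 1.5, 2.5]), RATE, 200)
        assert np.allclose(tensor.envelopes_mV, 1.0)

    def test_linear_ramp_resamples_linearly(self):
        n = int(2 * RATE)
        env = np.linspace(0.0, 1.0, n)[:, None]
        tensor = segment_and_normalize(env, GaitEvents([0.0, 2.0]), RATE, 200)
        expected = np.linspace(0.0, 1.0, 200)
        assert np.allclose(tensor.envelopes_mV[0, :, 0], expected, atol=1e-3)

    def test_degenerate_cycle_rejected(self):
        env = np.ones((1000, 2))
        with pytest.raises(DegenerateCycleError):
            segment_and_normalize(env, GaitEvents([0.1, 0.1005]), RATE, 200)


class TestAmplitudeNormalization:
    def test_shared_divisor_across_conditions(self):
        t1 = make_tensor(0.4 * np.ones((3, 200, 2)))
        t2 = make_tensor(0.8 * np.ones((3, 200, 2)))
        normalize_amplitude([t1, t2])
        assert np.allclose(t1.envelopes_norm, 0.5)
        assert np.allclose(t2.envelopes_norm, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        data = np.abs(rng.standard_normal((4, 200, 3)))
        a, b = make_tensor(data), make_tensor(3.0 * data)
        normalize_amplitude([a])
        normalize_amplitude([b])
        assert np.allclose(a.envelopes_norm, b.envelopes_norm)

    def test_all_zero_muscle_flagged_not_raised(self):
        data = np.abs(np.random.default_rng(2).standard_normal((3, 200, 2)))
        data[:, :, 1] = 0.0
        t = make_tensor(data)
        normalize_amplitude([t])
        assert t.excluded_muscles == ["R_ch1"]
        assert np.all(np.isfinite(t.envelopes_norm))

    def test_idempotent(self):
        data = np.abs(np.random.default_rng(4).standard_normal((3, 200, 2)))
        t = make_tensor(data)
        normalize_amplitude([t])
        once = t.envelopes_norm.copy()
        t2 = make_tensor(once)
        normalize_amplitude([t2])
        assert np.allclose(t2.envelopes_norm, once)


class TestOutlierCycles:
    @staticmethod
    def tensor_with_outlier(bad_cycle=4):
        base = np.stack([np.sin(np.linspace(0, np.pi, 200)) + 0.2] * 3, axis=1)
        data = np.stack([base] * 10)
        rng = np.random.default_rng(0)
        data[bad_cycle] = np.abs(rng.standard_normal((200, 3)))
        return make_tensor(data)

    def test_exactly_the_corrupt_cycle_flagged(self):
        report = detect_outlier_cycles(self.tensor_with_outlier(), 0.6)
        assert report.flagged_cycles == [4]
        assert report.excluded_cycles == [4]

    def test_identical_cycles_unflagged(self):
        data = np.stack([np.abs(np.random.default_rng(1).standard_normal((200, 2)))] * 5)
        report = detect_outlier_cycles(make_tensor(data), 0.6)
        assert report.flagged_cycles == []

    def test_threshold_is_strict_less_than(self):
        # build a cycle whose correlation with the ensemble is exactly the
        # threshold: flagging requires r < threshold, so it must survive
        report = detect_outlier_cycles(self.tensor_with_outlier(), 0.6)
        r_exact = float(np.nanmin(report.cycle_muscle_r[0]))
        report2 = detect_outlier_cycles(self.tensor_with_outlier(), r_exact)
        assert 0 not in report2.flagged_cycles

    def test_zero_variance_cycle_flagged_with_reason(self):
        data = np.stack([np.abs(np.random.default_rng(2).standard_normal((200, 2)))] * 4)
        data[1] = 1.0
        report = detect_outlier_cycles(make_tensor(data), 0.6)
        assert 1 in report.flagged_cycles
        assert "zero-variance" in report.flag_reasons[1]

    def test_needs_three_cycles(self):
        with pytest.raises(InsufficientCyclesError):
            detect_outlier_cycles(make_tensor(np.ones((2, 200, 2))), 0.6)


class TestQualityGate:
    @pytest.mark.parametrize(
        "excluded, total, expect",
        [(6, 10, True), (1, 20, False), (0, 10, False), (5, 10, False)],
    )
    def test_gate_on_excluded_fraction(self, excluded, total, expect):
        report = detect_outlier_cycles(
            make_tensor(np.abs(np.random.default_rng(0).standard_normal((total, 200, 2)))),
            0.6,
        )
        report.excluded_cycles = list(range(excluded))
        report.n_cycles = total
        gated = apply_quality_gate(report, PipelineConfig())
        assert gated.subject_excluded is expect


class TestHeelTouchdown:
    def test_sinusoidal_minima_found(self):
        t = np.arange(int(4 * RATE)) / RATE
        height = np.cos(2 * np.pi * (t - 1.0))  # minima at 0.5+k? cos min at pi
        events = detect_touchdown_from_heel(height, RATE)
        expected = [0.5, 1.5, 2.5, 3.5]
        assert np.allclose(events.touchdown_times, expected, atol=1.5 / RATE)

    def test_monotone_trajectory_fails(self):
        with pytest.raises(InsufficientCyclesError):
            detect_touchdown_from_heel(np.linspace(1, 0, 4000), RATE)

    def test_robust_to_small_noise_with_refractory(self):
        t = np.arange(int(4 * RATE)) / RATE
        rng = np.random.default_rng(5)
        height = np.cos(2 * np.pi * t) + 0.05 * rng.standard_normal(t.size)
        events = detect_touchdown_from_heel(height, RATE, refractory_s=0.3)
        clean = detect_touchdown_from_heel(np.cos(2 * np.pi * t), RATE)
        assert events.n_cycles == clean.n_cycles
        assert np.allclose(events.touchdown_times, clean.touchdown_times, atol=0.05)
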