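"""Peak-based step detection and step-interval quantization."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitbelt.data_io import AccelerometerRecording
from gaitbelt.exceptions import (
    EmptyRecordingError,
    InsufficientStepsError,
    ParameterError,
)
from gaitbelt.step_detection import (
    DetectionConfig,
    StepSeries,
    acceleration_magnitude,
    detect_steps,
    step_intervals,
)
from gaitbelt.synthetic_data import WalkSignalSpec, simulate_walk_signal

START = dt.datetime(2019, 1, 7, 9, 0)


def _recording(samples, fs=50.0):
    return AccelerometerRecording("p", fs, START, np.asarray(samples, float))


def brute_force_detect(x, fs, config):
    """Independent oracle: enumerate strict local maxima, compute prominence
    from its definition, then apply the greedy separation rule."""
    x = np.asarray(x, float)
    maxima = [i for i in range(1, len(x) - 1) if x[i - 1] < x[i] > x[i + 1]]
    kept_candidates = []
    for i in maxima:
        # walk left/right to the nearest strictly higher sample (or edge)
        left = i
        while left > 0 and x[left - 1] <= x[i]:
            left -= 1
        right = i
        while right < len(x) - 1 and x[right + 1] <= x[i]:
            right += 1
        left_base = x[left:i].min() if left < i else x[i]
        right_base = x[i + 1:right + 1].min() if right > i else x[i]
        prominence = x[i] - max(left_base, right_base)
        if prominence >= config.min_prominence:
            kept_candidates.append(i)
    min_gap = config.min_peak_separation * fs
    kept = []
    for i in sorted(kept_candidates, key=lambda j: (-x[j], j)):
        if all(abs(i - k) >= min_gap - 1e-9 for k in kept):
            kept.append(i)
    return np.array(sorted(kept)) / fs


class TestMagnitude:
    def test_constant_gravity_vector_maps_to_zero(self):
        rec = _recording([[0, 0, 1]] * 10)
        np.testing.assert_allclose(acceleration_magnitude(rec), 0.0)

    def test_pythagorean_sample_among_zeros(self):
        samples = [[0, 0, 0]] * 9
        samples.insert(4, [3, 4, 0])
        out = acceleration_magnitude(_recording(samples))
        assert out[4] == pytest.approx(5.0)  # median of the rest is 0

    def test_matches_generator_closed_form(self):
        spec = WalkSignalSpec(cadence=2.0, duration=5.0, noise_sd=0.0, seed=0)
        rec, _ = simulate_walk_signal(spec)
        t = rec.sample_times()
        z = (1.0 - spec.peak_amplitude * np.cos(2 * np.pi * spec.cadence * t)
             + spec.harmonic_fraction * spec.peak_amplitude
             * np.cos(4 * np.pi * spec.cadence * t))
        expected = z - np.median(z)
        np.testing.assert_allclose(acceleration_magnitude(rec), expected, atol=1e-9)

    def test_empty_recording_rejected(self):
        rec = AccelerometerRecording("p", 50.0, START, np.empty((0, 3)))
        with pytest.raises(EmptyRecordingError):
            acceleration_magnitude(rec)


class TestDetectSteps:
    def test_flat_signal_has_no_steps(self):
        steps = detect_steps(np.zeros(500), 50.0)
        assert steps.n_steps == 0

    def test_pure_sinusoid_recovers_every_cycle_peak(self):
        spec = WalkSignalSpec(
            cadence=1.8, duration=10.0, peak_amplitude=0.5,
            harmonic_fraction=0.0, noise_sd=0.0, seed=0,
        )
        rec, truth = simulate_walk_signal(spec)
        steps = detect_steps(acceleration_magnitude(rec), rec.sampling_rate)
        assert steps.n_steps == truth.size == 18
        half_sample = 0.5 / rec.sampling_rate
        assert np.abs(steps.step_times - truth).max() <= half_sample + 1e-9

    def test_close_pair_keeps_only_higher_peak(self):
        fs = 100.0
        x = np.zeros(300)
        x[100] = 0.5   # t = 1.0 s
        x[110] = 0.4   # t = 1.1 s, within min separation
        config = DetectionConfig(smoothing_window=0.0, min_peak_separation=0.25)
        steps = detect_steps(x, fs, config)
        np.testing.assert_allclose(steps.step_times, [1.0])

    def test_equal_heights_keep_earlier_peak(self):
        fs = 100.0
        x = np.zeros(300)
        x[100] = 0.5
        x[110] = 0.5
        config = DetectionConfig(smoothing_window=0.0, min_peak_separation=0.25)
        steps = detect_steps(x, fs, config)
        np.testing.assert_allclose(steps.step_times, [1.0])

    @pytest.mark.parametrize("case", range(20))
    def test_equivalent_to_brute_force_oracle(self, case):
        rng = np.random.default_rng(1000 + case)
        raw = rng.normal(0, 1, 300)
        kernel = np.exp(-0.5 * (np.arange(-10, 11) / 4.0) ** 2)
        x = np.convolve(raw, kernel / kernel.sum(), mode="same")
        config = DetectionConfig(
            smoothing_window=0.0, min_peak_separation=0.3, min_prominence=0.2
        )
        detected = detect_steps(x, 50.0, config).step_times
        expected = brute_force_detect(x, 50.0, config)
        np.testing.assert_allclose(detected, expected)

    def test_translation_equivariance(self):
        spec = WalkSignalSpec(cadence=2.0, duration=5.0, noise_sd=0.0, seed=0)
        rec, _ = simulate_walk_signal(spec)
        x = acceleration_magnitude(rec)
        shift = 50  # 1 s of baseline prepended
        padded = np.concatenate([np.full(shift, x.min()), x])
        base = detect_steps(x, 50.0).step_times
        moved = detect_steps(padded, 50.0).step_times
        np.testing.assert_allclose(moved, base + shift / 50.0)

    def test_amplitude_scaling_never_removes_steps(self):
        rng = np.random.default_rng(7)
        spec = WalkSignalSpec(cadence=1.8, duration=10.0, noise_sd=0.05, seed=9)
        rec, _ = simulate_walk_signal(spec)
        x = acceleration_magnitude(rec)
        base = set(np.round(detect_steps(x, 50.0).step_times, 6))
        scaled = set(np.round(detect_steps(3.0 * x, 50.0).step_times, 6))
        assert base <= scaled

    @pytest.mark.parametrize("cadence", [1.0, 1.3, 1.8, 2.5, 3.0])
    def test_zero_noise_count_matches_generator(self, cadence):
        spec = WalkSignalSpec(cadence=cadence, duration=30.0, noise_sd=0.0, seed=0)
        rec, truth = simulate_walk_signal(spec)
        steps = detect_steps(acceleration_magnitude(rec), rec.sampling_rate)
        assert steps.n_steps == truth.size

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            detect_steps(np.zeros(100), 0.0)
        with pytest.raises(ParameterError):
            detect_steps(np.zeros(1), 50.0)
        with pytest.raises(ParameterError):
            DetectionConfig(min_peak_separation=0.0)
        with pytest.raises(ParameterError):
            DetectionConfig(smoothing_window=-1.0)
        with pytest.raises(ParameterError):
            DetectionConfig(band=(3.0, 0.5))

    def test_band_pass_still_finds_walking_peaks(self):
        spec = WalkSignalSpec(cadence=2.0, duration=20.0, noise_sd=0.0, seed=0)
        rec, truth = simulate_walk_signal(spec)
        config = DetectionConfig(band=(0.5, 3.0))
        steps = detect_steps(acceleration_magnitude(rec), 50.0, config)
        assert steps.n_steps == truth.size


class TestStepIntervals:
    def test_rounding_to_tenth_with_ties_up(self):
        np.testing.assert_allclose(
            step_intervals(np.array([0.0, 0.52, 1.09])), [0.5, 0.6]
        )
        np.testing.assert_allclose(step_intervals(np.array([0.0, 0.25])), [0.3])

    def test_degenerate_interval_clamped_to_grid_minimum(self):
        np.testing.assert_allclose(step_intervals(np.array([0.0, 0.04])), [0.1])

    def test_fewer_than_two_steps_rejected(self):
        with pytest.raises(InsufficientStepsError):
            step_intervals(np.array([1.0]))

    def test_accepts_step_series(self):
        series = StepSeries("p", np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(step_intervals(series), [0.5, 0.5])

    @given(
        st.lists(st.floats(min_value=0.25, max_value=2.0), min_size=1, max_size=60)
    )
    def test_quantization_property(self, gaps):
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        q = step_intervals(times)
        raw = np.diff(times)
        assert np.all(q > 0)
        # positive multiples of 0.1
        np.testing.assert_allclose(np.round(q * 10) - q * 10, 0.0, atol=1e-9)
        assert np.all(np.abs(q - raw) <= 0.05 + 1e-9)
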