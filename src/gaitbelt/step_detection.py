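"""Peak-based step detection on triaxial accelerometer signals.

The detector works on the gravity-removed acceleration *magnitude*
``sqrt(ax**2 + ay**2 + az**2) - median``, which is invariant to the (stable
but unknown) orientation of a belt-worn sensor.  Candidate peaks come from
prominence-filtered local maxima; a minimum peak separation then enforces a
physiological cadence ceiling.  Each retained peak is one step.

Step intervals — the elapsed time between consecutive peaks — are quantized
to a 0.1-second grid, matching the resolution at which the downstream speed
model consumes them: ties (x.x5) round up, and an interval that would round
to zero is clamped to 0.1 s, since a step interval cannot be zero.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
from scipy import signal as sps

from .data_io import DEFAULT_START_TIME, AccelerometerRecording
from .exceptions import (
    EmptyRecordingError,
    InsufficientStepsError,
    ParameterError,
    ValidationError,
)

#: Grid spacing of quantized step intervals, seconds.
INTERVAL_QUANTUM = 0.1


@dataclasses.dataclass
class DetectionConfig:
    """Tunable parameters of the peak detector.

    Attributes
    ----------
    smoothing_window : float
        Moving-average width in seconds (0 disables smoothing).  The window
        is forced to an odd sample count so smoothing never shifts a
        symmetric peak.
    min_peak_separation : float
        Minimum time between retained peaks, seconds.  The default 0.25 s
        caps cadence at 4 steps/s, the ceiling of normal human walking.
    min_prominence : float
        Minimum topographic prominence of a peak, in g.
    band : tuple of (low, high) or None
        Optional Butterworth band-pass corner frequencies in Hz
        (off by default).
    """

    smoothing_window: float = 0.15
    min_peak_separation: float = 0.25
    min_prominence: float = 0.05
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.min_peak_separation <= 0:
            raise ParameterError("min_peak_separation must be > 0")
        if self.smoothing_window < 0:
            raise ParameterError("smoothing_window must be >= 0")
        if self.min_prominence < 0:
            raise ParameterError("min_prominence must be >= 0")
        if self.band is not None:
            low, high = self.band
            if not 0 < low < high:
                raise ParameterError(f"band must satisfy 0 < low < high, got {self.band}")


@dataclasses.dataclass
class StepSeries:
    """Detected step event times, seconds since the recording start."""

    participant_id: str
    step_times: np.ndarray
    recording_start: dt.datetime = DEFAULT_START_TIME

    def __post_init__(self) -> None:
        self.step_times = np.asarray(self.step_times, dtype=float)
        if self.step_times.size and (
            np.any(np.diff(self.step_times) <= 0) or self.step_times[0] < 0
        ):
            raise ValidationError("step_times must be non-negative and strictly increasing")

    @property
    def n_steps(self) -> int:
        return int(self.step_times.size)


def acceleration_magnitude(recording: AccelerometerRecording) -> np.ndarray:
    """Gravity-removed signed magnitude of a triaxial recording.

    Returns ``sqrt(ax**2 + ay**2 + az**2)`` minus the series median.  For a
    device at rest the magnitude is the constant 1 g of gravity, so median
    subtraction serves as baseline (gravity) removal without assuming which
    axis points down.
    """
    if recording.n_samples == 0:
        raise EmptyRecordingError("cannot compute magnitude of an empty recording")
    magnitude = np.linalg.norm(recording.samples, axis=1)
    return magnitude - np.median(magnitude)


def _smooth(x: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    n = int(round(window_s * fs))
    if n <= 1:
        return x
    if n % 2 == 0:  # odd window keeps symmetric peaks in place
        n += 1
    kernel = np.full(n, 1.0 / n)
    return np.convolve(x, kernel, mode="same")


def _enforce_separation(
    peaks: np.ndarray, heights: np.ndarray, min_gap_samples: float
) -> np.ndarray:
    """Greedy separation filter: taller peaks win; ties keep the earlier peak."""
    order = np.lexsort((peaks, -heights))
    kept: list[int] = []
    for idx in peaks[order]:
        if all(abs(idx - other) >= min_gap_samples - 1e-9 for other in kept):
            kept.append(int(idx))
    return np.array(sorted(kept), dtype=int)


def detect_steps(
    signal: np.ndarray,
    sampling_rate: float,
    config: DetectionConfig | None = None,
    participant_id: str = "unknown",
    recording_start: dt.datetime = DEFAULT_START_TIME,
) -> StepSeries:
    """Detect steps as prominence- and separation-filtered signal peaks.

    Parameters
    ----------
    signal : array
        Gravity-removed magnitude (see :func:`acceleration_magnitude`), in g.
    sampling_rate : float
        Samples per second.
    config : DetectionConfig, optional
        Detector parameters; defaults are tuned for normal adult walking.

    Returns
    -------
    StepSeries
        Step times at ``peak_index / sampling_rate``, strictly increasing.

    Notes
    -----
    When two candidate peaks fall closer than ``min_peak_separation``, the
    taller one is kept; at equal height the earlier one wins, making the
    result deterministic.
    """
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be strictly positive")
    config = config or DetectionConfig()
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ParameterError("signal must contain at least 2 samples")
    if config.band is not None:
        low, high = config.band
        if high >= sampling_rate / 2:
            raise ParameterError(
                f"band high edge {high} Hz must be below Nyquist ({sampling_rate / 2} Hz)"
            )
        sos = sps.butter(2, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
        x = sps.sosfiltfilt(sos, x)
    x = _smooth(x, config.smoothing_window, sampling_rate)
    peaks, _ = sps.find_peaks(x, prominence=config.min_prominence or None)
    if peaks.size:
        peaks = _enforce_separation(
            peaks, x[peaks], config.min_peak_separation * sampling_rate
        )
    return StepSeries(
        participant_id=participant_id,
        step_times=peaks / sampling_rate,
        recording_start=recording_start,
    )


def step_intervals(steps: StepSeries | np.ndarray) -> np.ndarray:
    """Quantized intervals between consecutive steps, in seconds.

    Raw differences are rounded to the nearest multiple of 0.1 s with ties
    rounding up; a post-rounding zero is clamped to 0.1 s.  Every returned
    value is therefore a positive multiple of 0.1.

    Raises
    ------
    InsufficientStepsError
        Fewer than two step times.
    """
    times = steps.step_times if isinstance(steps, StepSeries) else np.asarray(steps, float)
    if times.size < 2:
        raise InsufficientStepsError("at least two steps are needed to form an interval")
    raw = np.diff(times)
    if np.any(raw <= 0):
        raise ValidationError("step times must be strictly increasing")
    grid = np.floor(raw / INTERVAL_QUANTUM + 0.5)  # floor(x + .5): ties round up
    grid = np.maximum(grid, 1.0)
    return grid * INTERVAL_QUANTUM
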