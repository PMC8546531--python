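"""Walking bouts and bout-level gait speed from detected steps.

The speed model follows the classic pedometry convention: step length is a
sex-specific constant times body height (0.415 for men, 0.413 for women),
and the instantaneous speed of each step is step length divided by the
quantized step interval.  One *walking bout* — a maximal run of steps with
no inter-step gap beyond a threshold — yields one gait speed measurement:
the arithmetic mean of its per-step speeds, stamped with the bout's start
time so that time-of-day and day-of-week context can be derived.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np

from .data_io import AccelerometerRecording
from .exceptions import InsufficientStepsError, ParameterError, ValidationError
from .step_detection import DetectionConfig, StepSeries, acceleration_magnitude, detect_steps, step_intervals

#: Step length as a fraction of body height, by sex (pedometry convention).
STEP_LENGTH_CONSTANTS = {"male": 0.415, "female": 0.413}

#: Default bout segmentation: gaps above 2.5 s split bouts; runs shorter
#: than 8 steps (~4 s of walking) are discarded as shuffles or single steps.
DEFAULT_MAX_GAP = 2.5
DEFAULT_MIN_STEPS = 8

_DAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def step_length(
    height: float, sex: str, constants: dict[str, float] | None = None
) -> float:
    """Estimated step length in meters: ``k_sex * height``.

    Parameters
    ----------
    height : float
        Body height in meters, within [1.0, 2.5].
    sex : {"male", "female"}
    constants : dict, optional
        Override of :data:`STEP_LENGTH_CONSTANTS`.
    """
    if not 1.0 <= height <= 2.5:
        raise ValidationError(f"height {height} m outside [1.0, 2.5]")
    table = constants if constants is not None else STEP_LENGTH_CONSTANTS
    if sex not in table:
        raise ValidationError(f"unknown sex token {sex!r}")
    return table[sex] * height


@dataclasses.dataclass
class WalkingBout:
    """A maximal run of contiguous steps forming one speed measurement."""

    participant_id: str
    start_time: dt.datetime
    end_time: dt.datetime
    step_times: np.ndarray  # seconds since recording start

    def __post_init__(self) -> None:
        self.step_times = np.asarray(self.step_times, dtype=float)
        if self.end_time <= self.start_time:
            raise ValidationError("bout duration must be positive")

    @property
    def n_steps(self) -> int:
        return int(self.step_times.size)

    @property
    def duration(self) -> float:
        """Seconds from first to last step."""
        return float(self.step_times[-1] - self.step_times[0])


@dataclasses.dataclass
class GaitSpeedMeasurement:
    """One bout-level gait speed value with calendar context.

    ``hour_of_day``, ``day_of_week`` and ``is_weekend`` are always derived
    from ``timestamp`` (local clock), never supplied independently.
    """

    participant_id: str
    timestamp: dt.datetime
    speed: float
    duration: float
    n_steps: int
    hour_of_day: int = dataclasses.field(init=False)
    day_of_week: str = dataclasses.field(init=False)
    is_weekend: bool = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValidationError(f"speed must be positive, got {self.speed}")
        if self.duration < 0:
            raise ValidationError("duration must be non-negative")
        self.hour_of_day = self.timestamp.hour
        weekday = self.timestamp.weekday()
        self.day_of_week = _DAY_NAMES[weekday]
        self.is_weekend = weekday >= 5


def segment_bouts(
    steps: StepSeries,
    max_gap: float = DEFAULT_MAX_GAP,
    min_steps: int = DEFAULT_MIN_STEPS,
) -> list[WalkingBout]:
    """Split a step series into maximal runs with gaps <= ``max_gap``.

    Runs shorter than ``min_steps`` are discarded.  Bouts are returned in
    chronological order and never overlap.
    """
    if max_gap <= 0:
        raise ParameterError("max_gap must be > 0")
    if min_steps < 2:
        raise ParameterError("min_steps must be >= 2")
    times = steps.step_times
    if times.size == 0:
        return []
    breaks = np.nonzero(np.diff(times) > max_gap)[0] + 1
    bouts = []
    for run in np.split(times, breaks):
        if run.size < min_steps:
            continue
        bouts.append(
            WalkingBout(
                participant_id=steps.participant_id,
                start_time=steps.recording_start + dt.timedelta(seconds=float(run[0])),
                end_time=steps.recording_start + dt.timedelta(seconds=float(run[-1])),
                step_times=run,
            )
        )
    return bouts


def bout_speed(bout: WalkingBout, step_length_m: float) -> GaitSpeedMeasurement:
    """Bout-level speed: mean of per-step speeds ``step_length / interval``.

    Intervals are the quantized step intervals (0.1-s grid); duration is the
    raw first-to-last step time; the timestamp is the bout start.
    """
    if step_length_m <= 0:
        raise ParameterError("step_length_m must be > 0")
    if bout.n_steps < 2:
        raise InsufficientStepsError("a bout needs at least two steps")
    intervals = step_intervals(bout.step_times)
    speeds = step_length_m / intervals
    return GaitSpeedMeasurement(
        participant_id=bout.participant_id,
        timestamp=bout.start_time,
        speed=float(np.mean(speeds)),
        duration=bout.duration,
        n_steps=bout.n_steps,
    )


def measure_recording(
    recording: AccelerometerRecording,
    height: float,
    sex: str,
    config: DetectionConfig | None = None,
    max_gap: float = DEFAULT_MAX_GAP,
    min_steps: int = DEFAULT_MIN_STEPS,
) -> list[GaitSpeedMeasurement]:
    """Full chain: magnitude -> step detection -> bouts -> speeds."""
    magnitude = acceleration_magnitude(recording)
    steps = detect_steps(
        magnitude,
        recording.sampling_rate,
        config=config,
        participant_id=recording.participant_id,
        recording_start=recording.start_time,
    )
    length = step_length(height, sex)
    return [bout_speed(b, length) for b in segment_bouts(steps, max_gap, min_steps)]
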