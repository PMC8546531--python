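"""Tabular I/O: accelerometer recordings, participant tables, measurement files.

File dialects
-------------
accelerometer CSV
    columns ``t,ax,ay,az`` — axes in units of g; ``t`` is optional and
    ignored (sample times follow from the supplied sampling rate).
participant CSV
    ``participant_id,sex,age,height_m,weight_kg,grip1_kg,grip2_kg,grip3_kg,
    asm_kg,usual_gait_speed_ms,hypertension,diabetes,angina,arthritis,smoking``
    (optional trailing ``wear_days``).
measurements CSV
    ``participant_id,timestamp,speed_ms,duration_s,n_steps,day_of_week,
    hour_of_day`` with speeds written to three decimals.

Timestamps are timezone-naive local time throughout: time-of-day and
day-of-week context is meant to reflect the wearer's local clock.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyRecordingError,
    FormatError,
    ParameterError,
    ParseError,
    ValidationError,
)

AXIS_COLUMNS = ("ax", "ay", "az")

PARTICIPANT_COLUMNS = (
    "participant_id", "sex", "age", "height_m", "weight_kg",
    "grip1_kg", "grip2_kg", "grip3_kg", "asm_kg", "usual_gait_speed_ms",
    "hypertension", "diabetes", "angina", "arthritis", "smoking",
)

MEASUREMENT_COLUMNS = (
    "participant_id", "timestamp", "speed_ms", "duration_s",
    "n_steps", "day_of_week", "hour_of_day",
)

#: Fallback anchor when a recording carries no wall-clock start time.
DEFAULT_START_TIME = dt.datetime(2019, 1, 7, 0, 0, 0)

_SEX_TOKENS = {"male": "male", "m": "male", "female": "female", "f": "female"}
_SMOKING_TOKENS = ("current", "ex", "never")
_TRUE_TOKENS = {"1", "true", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "no", "n", ""}


@dataclasses.dataclass
class AccelerometerRecording:
    """A uniformly sampled triaxial acceleration trace.

    Sample ``i`` occurs at ``start_time + i / sampling_rate``; recordings
    with gaps must be split upstream before construction.

    Attributes
    ----------
    participant_id : str
        Opaque identifier.
    sampling_rate : float
        Samples per second, strictly positive.
    start_time : datetime.datetime
        Local wall-clock time of the first sample (timezone-naive).
    samples : numpy.ndarray, shape (n, 3)
        Acceleration in units of g, axis order (ax, ay, az).
    """

    participant_id: str
    sampling_rate: float
    start_time: dt.datetime
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be strictly positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError(
                f"samples must have shape (n, 3); got {self.samples.shape}"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration(self) -> float:
        """Time spanned by the samples: ``(n - 1) / sampling_rate`` seconds."""
        n = self.n_samples
        return (n - 1) / self.sampling_rate if n > 0 else 0.0

    def sample_times(self) -> np.ndarray:
        """Seconds of each sample since ``start_time``."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclasses.dataclass
class ParticipantProfile:
    """Anthropometrics and clinical measurements for one participant.

    ``height`` is in meters and restricted to [1.0, 2.5]; heights entered in
    centimeters are rejected rather than silently rescaled.  The appendicular
    skeletal muscle (ASM) index is always recomputed from ``asm`` and
    ``height`` — a file-supplied index is never trusted.
    """

    participant_id: str
    sex: str
    age: float
    height: float
    weight: float
    handgrip_trials: tuple[float, float, float] | None = None
    asm: float | None = None
    usual_gait_speed: float | None = None
    wear_days: int | None = None
    hypertension: bool = False
    diabetes: bool = False
    angina: bool = False
    arthritis: bool = False
    smoking: str = "never"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"unknown sex token {self.sex!r}")
        if not 1.0 <= self.height <= 2.5:
            raise ValidationError(
                f"height {self.height} m outside [1.0, 2.5]; "
                "centimeter entries must be converted upstream"
            )
        for name in ("age", "weight", "asm", "usual_gait_speed"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {value}")
        if self.handgrip_trials is not None:
            trials = tuple(float(v) for v in self.handgrip_trials)
            if len(trials) != 3 or any(v <= 0 for v in trials):
                raise ValidationError(
                    f"handgrip_trials must be three positive values, got {trials}"
                )
            self.handgrip_trials = trials
        if self.smoking not in _SMOKING_TOKENS:
            raise ValidationError(f"unknown smoking token {self.smoking!r}")

    @property
    def asm_index(self) -> float | None:
        """ASM / height**2 in kg/m**2, recomputed from the stored fields."""
        if self.asm is None:
            return None
        return self.asm / self.height**2


def _parse_flag(token: object, row: int, column: str) -> bool:
    text = str(token).strip().lower()
    if text in _TRUE_TOKENS:
        return True
    if text in _FALSE_TOKENS:
        return False
    raise ParseError(f"row {row}: cannot parse {column}={token!r} as a flag")


def read_accelerometer_csv(
    path: str | Path,
    sampling_rate: float,
    start_time: dt.datetime | None = None,
    participant_id: str | None = None,
) -> AccelerometerRecording:
    """Read a triaxial acceleration CSV into a recording.

    Parameters
    ----------
    path : path-like
        CSV with header columns ``ax, ay, az`` (a ``t`` column is ignored).
    sampling_rate : float
        Samples per second, supplied out-of-band and strictly positive.
    start_time : datetime, optional
        Wall-clock anchor of the first sample; defaults to
        :data:`DEFAULT_START_TIME`.
    participant_id : str, optional
        Overrides a ``participant_id`` column; falls back to the file stem.

    Raises
    ------
    FormatError
        A required axis column is missing.
    ParseError
        A cell is non-numeric or blank (the message names the file row).
    EmptyRecordingError
        The file has a header but no samples, or is entirely empty.
    """
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be strictly positive")
    path = Path(path)
    try:
        # round_trip parsing: written samples must re-read bit-identically
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise EmptyRecordingError(f"{path}: no data") from exc
    for column in AXIS_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column '{column}'")
    if len(frame) == 0:
        raise EmptyRecordingError(f"{path}: file contains no samples")
    axes = []
    for column in AXIS_COLUMNS:
        numeric = pd.to_numeric(frame[column], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            # +2: one for the header line, one for 0-based indexing
            row = int(bad.idxmax()) + 2
            raise ParseError(
                f"{path}: row {row}: cannot parse '{column}' value "
                f"{frame[column].iloc[int(bad.idxmax())]!r} as a number"
            )
        axes.append(numeric.to_numpy(dtype=float))
    if participant_id is None:
        if "participant_id" in frame.columns:
            ids = frame["participant_id"].unique()
            if len(ids) != 1:
                raise ValidationError(f"{path}: multiple participant ids {ids!r}")
            participant_id = str(ids[0])
        else:
            participant_id = path.stem
    return AccelerometerRecording(
        participant_id=participant_id,
        sampling_rate=float(sampling_rate),
        start_time=start_time or DEFAULT_START_TIME,
        samples=np.column_stack(axes),
    )


def write_accelerometer_csv(recording: AccelerometerRecording, path: str | Path) -> None:
    """Write a recording as ``t,ax,ay,az`` with full float precision."""
    frame = pd.DataFrame(
        {
            "t": recording.sample_times(),
            "ax": recording.samples[:, 0],
            "ay": recording.samples[:, 1],
            "az": recording.samples[:, 2],
        }
    )
    frame.to_csv(path, index=False)


def _parse_participant_row(row: pd.Series, file_row: int) -> ParticipantProfile:
    sex_token = str(row["sex"]).strip().lower()
    if sex_token not in _SEX_TOKENS:
        raise ValidationError(f"row {file_row}: unknown sex token {row['sex']!r}")
    numeric = {}
    for column in ("age", "height_m", "weight_kg", "grip1_kg", "grip2_kg",
                   "grip3_kg", "asm_kg", "usual_gait_speed_ms"):
        try:
            numeric[column] = float(row[column]) if pd.notna(row[column]) else None
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"row {file_row}: cannot parse {column}={row[column]!r}"
            ) from exc
    trials = (numeric["grip1_kg"], numeric["grip2_kg"], numeric["grip3_kg"])
    wear_days = None
    if "wear_days" in row.index and pd.notna(row["wear_days"]):
        wear_days = int(row["wear_days"])
    return ParticipantProfile(
        participant_id=str(row["participant_id"]),
        sex=_SEX_TOKENS[sex_token],
        age=numeric["age"],
        height=numeric["height_m"],
        weight=numeric["weight_kg"],
        handgrip_trials=None if any(v is None for v in trials) else trials,
        asm=numeric["asm_kg"],
        usual_gait_speed=numeric["usual_gait_speed_ms"],
        wear_days=wear_days,
        hypertension=_parse_flag(row["hypertension"], file_row, "hypertension"),
        diabetes=_parse_flag(row["diabetes"], file_row, "diabetes"),
        angina=_parse_flag(row["angina"], file_row, "angina"),
        arthritis=_parse_flag(row["arthritis"], file_row, "arthritis"),
        smoking=str(row["smoking"]).strip().lower(),
    )


def read_participant_table(path: str | Path) -> list[ParticipantProfile]:
    """Read a participant CSV, validating every row against the invariants.

    Parsing is all-or-nothing: the first invalid row raises, so no row is
    ever silently dropped.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: no data") from exc
    for column in PARTICIPANT_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column '{column}'")
    profiles = []
    for index, row in frame.iterrows():
        profiles.append(_parse_participant_row(row, int(index) + 2))
    return profiles


def write_participant_table(
    profiles: Iterable[ParticipantProfile], path: str | Path
) -> None:
    rows = []
    for p in profiles:
        trials = p.handgrip_trials or (None, None, None)
        rows.append(
            {
                "participant_id": p.participant_id,
                "sex": p.sex,
                "age": p.age,
                "height_m": p.height,
                "weight_kg": p.weight,
                "grip1_kg": trials[0],
                "grip2_kg": trials[1],
                "grip3_kg": trials[2],
                "asm_kg": p.asm,
                "usual_gait_speed_ms": p.usual_gait_speed,
                "hypertension": int(p.hypertension),
                "diabetes": int(p.diabetes),
                "angina": int(p.angina),
                "arthritis": int(p.arthritis),
                "smoking": p.smoking,
                "wear_days": p.wear_days,
            }
        )
    pd.DataFrame(rows, columns=list(PARTICIPANT_COLUMNS) + ["wear_days"]).to_csv(
        path, index=False
    )


def write_measurements_csv(measurements: Sequence, path: str | Path) -> None:
    """Write gait speed measurements, one row each, speeds to 3 decimals.

    An empty sequence produces a header-only file.
    """
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(",".join(MEASUREMENT_COLUMNS) + "\n")
        for m in measurements:
            handle.write(
                f"{m.participant_id},{m.timestamp.isoformat()},"
                f"{m.speed:.3f},{m.duration:.3f},{m.n_steps},"
                f"{m.day_of_week},{m.hour_of_day}\n"
            )


def read_measurements_csv(path: str | Path) -> list:
    """Read a measurements CSV back into :class:`~gaitbelt.gait_speed.GaitSpeedMeasurement` objects.

    Calendar context (hour, day-of-week, weekend flag) is re-derived from the
    timestamp rather than trusted from the file.
    """
    from .gait_speed import GaitSpeedMeasurement  # local import: avoids a cycle

    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: no data") from exc
    for column in ("participant_id", "timestamp", "speed_ms", "duration_s", "n_steps"):
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column '{column}'")
    measurements = []
    for index, row in frame.iterrows():
        try:
            timestamp = dt.datetime.fromisoformat(str(row["timestamp"]))
        except ValueError as exc:
            raise ParseError(
                f"{path}: row {int(index) + 2}: bad timestamp {row['timestamp']!r}"
            ) from exc
        measurements.append(
            GaitSpeedMeasurement(
                participant_id=str(row["participant_id"]),
                timestamp=timestamp,
                speed=float(row["speed_ms"]),
                duration=float(row["duration_s"]),
                n_steps=int(row["n_steps"]),
            )
        )
    return measurements


def measurements_to_frame(measurements) -> pd.DataFrame:
    """Convert measurements to a DataFrame used by the analytics layer.

    Accepts a list of measurement objects or an already converted frame
    (returned unchanged).
    """
    if isinstance(measurements, pd.DataFrame):
        return measurements
    return pd.DataFrame(
        {
            "participant_id": [m.participant_id for m in measurements],
            "timestamp": [m.timestamp for m in measurements],
            "speed": [m.speed for m in measurements],
            "duration": [m.duration for m in measurements],
            "n_steps": [m.n_steps for m in measurements],
            "hour": [m.hour_of_day for m in measurements],
            "dow": [m.timestamp.weekday() for m in measurements],
            "is_weekend": [m.is_weekend for m in measurements],
            "date": [m.timestamp.date() for m in measurements],
        }
    )
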