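"""Daily-life gait descriptors aggregated from bout-level measurements.

Summaries mirror how free-living gait is typically reported: per-day walking
time and mean speed, a diurnal (time-of-day) profile, a weekday/weekend
split, dispersion of speed (SD and coefficient of variation), and each
participant's free-living speed expressed relative to their own supervised
walkway speed ("percentile vs usual": the median of the per-measurement
ratio x 100, with the fractions of measurements more than 25% faster or
slower than usual).

Participant-level statistics pool all measurements directly (not daily
means).  A wear-day is any calendar date with at least one measurement, and
eligibility requires a configurable minimum number of wear-days
(default 10).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import measurements_to_frame
from .exceptions import ParameterError, ValidationError

#: Twelve 2-hour time-of-day bins [1,3), [3,5), ..., [23,1): chosen so the
#: early-morning window 5-7 h is a single bin.
DEFAULT_BIN_EDGES = (1, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21, 23)

#: Decade age bins for cohort summaries: 50-59, 60-69, 70-79, 80+.
DEFAULT_AGE_EDGES = (50, 60, 70, 80)

DEFAULT_MIN_WEAR_DAYS = 10

_DAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


@dataclasses.dataclass
class DailyGaitSummary:
    participant_id: str
    date: dt.date
    mean_speed: float
    walking_time_min: float
    n_measurements: int


@dataclasses.dataclass
class PercentileSummary:
    """Free-living speed relative to the participant's usual gait speed."""

    percentile: float       # median of 100 * speed / usual
    pct_faster25: float     # % of measurements with ratio > 125
    pct_slower25: float     # % of measurements with ratio < 75


@dataclasses.dataclass
class WeeklySplit:
    weekday_mean: float | None
    weekend_mean: float | None
    weekday_walk_min: float | None  # minutes per observed weekday
    weekend_walk_min: float | None


@dataclasses.dataclass
class ParticipantGaitProfile:
    participant_id: str
    n_measurements: int
    mean_speed: float
    median_speed: float
    sd_speed: float
    cv_pct: float
    hourly_profile: dict
    dow_profile: dict
    weekday_mean: float | None
    weekend_mean: float | None
    weekday_walk_min: float | None
    weekend_walk_min: float | None
    percentile_vs_usual: float | None
    pct_faster25: float | None
    pct_slower25: float | None
    wear_days: int
    eligible: bool


def _frame(measurements) -> pd.DataFrame:
    frame = measurements_to_frame(measurements)
    if len(frame) == 0:
        raise ParameterError("at least one measurement is required")
    return frame


def aggregate_daily(measurements) -> list[DailyGaitSummary]:
    """One summary row per calendar date with at least one measurement.

    ``mean_speed`` is the unweighted mean over the date's measurements and
    ``walking_time_min`` the sum of bout durations in minutes.  All
    measurements must belong to a single participant.
    """
    frame = _frame(measurements)
    pids = frame["participant_id"].unique()
    if len(pids) != 1:
        raise ValidationError(f"expected one participant, got {sorted(map(str, pids))}")
    out = []
    for date, group in frame.groupby("date", sort=True):
        out.append(
            DailyGaitSummary(
                participant_id=str(pids[0]),
                date=date,
                mean_speed=float(group["speed"].mean()),
                walking_time_min=float(group["duration"].sum() / 60.0),
                n_measurements=int(len(group)),
            )
        )
    return out


def percentile_vs_usual(measurements, usual_gait_speed: float) -> PercentileSummary:
    """Summarize free-living speeds relative to the usual (walkway) speed.

    The per-measurement ratio is ``100 * speed / usual``; the headline
    "percentile" is the median ratio.  The faster/slower fractions use
    strict inequalities (ratio > 125, ratio < 75).
    """
    if usual_gait_speed <= 0:
        raise ParameterError("usual_gait_speed must be > 0")
    if isinstance(measurements, (np.ndarray, list, tuple)) and not (
        len(measurements) and hasattr(measurements[0], "speed")
    ):
        speeds = np.asarray(measurements, dtype=float)
    else:
        speeds = _frame(measurements)["speed"].to_numpy()
    if speeds.size == 0:
        raise ParameterError("at least one measurement is required")
    ratios = 100.0 * speeds / usual_gait_speed
    n = ratios.size
    return PercentileSummary(
        percentile=float(np.median(ratios)),
        pct_faster25=100.0 * int(np.sum(ratios > 125.0)) / n,
        pct_slower25=100.0 * int(np.sum(ratios < 75.0)) / n,
    )


def _make_bins(bin_edges: Sequence[int]) -> list[tuple[int, int]]:
    edges = list(bin_edges)
    if len(edges) < 1 or edges != sorted(set(edges)) or not all(
        isinstance(e, (int, np.integer)) and 0 <= e <= 23 for e in edges
    ):
        raise ParameterError(
            f"bin edges must be strictly increasing integer hours in [0, 23], got {bin_edges!r}"
        )
    bins = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    bins.append((edges[-1], edges[0]))  # wrap-around bin
    return bins


def _hour_in_bin(hour: int, lo: int, hi: int) -> bool:
    if lo < hi:
        return lo <= hour < hi
    return hour >= lo or hour < hi  # wrap across midnight


def diurnal_profile(
    measurements,
    bin_edges: Sequence[int] | None = None,
    return_counts: bool = False,
) -> dict:
    """Mean speed per time-of-day bin.

    ``bin_edges`` are integer hours partitioning the 24-h clock; consecutive
    edges form half-open bins and the last edge wraps to the first.  Empty
    bins are reported as ``None`` (missing), never as zero.  With
    ``return_counts`` each value is ``(mean, count)`` instead.
    """
    frame = _frame(measurements)
    bins = _make_bins(bin_edges if bin_edges is not None else DEFAULT_BIN_EDGES)
    hours = frame["hour"].to_numpy()
    speeds = frame["speed"].to_numpy()
    profile: dict = {}
    for lo, hi in bins:
        mask = np.fromiter((_hour_in_bin(int(h), lo, hi) for h in hours), bool, len(hours))
        n = int(mask.sum())
        mean = float(speeds[mask].mean()) if n else None
        profile[(lo, hi)] = (mean, n) if return_counts else mean
    return profile


def weekly_split(measurements) -> WeeklySplit:
    """Weekday (Mon-Fri) vs weekend (Sat-Sun) speed means and walking minutes.

    Walking minutes are per observed calendar day within each partition.
    An empty partition yields ``None`` for its fields.
    """
    frame = _frame(measurements)

    def summarize(part: pd.DataFrame) -> tuple[float | None, float | None]:
        if len(part) == 0:
            return None, None
        days = part["date"].nunique()
        return (
            float(part["speed"].mean()),
            float(part["duration"].sum() / 60.0 / days),
        )

    weekday_mean, weekday_min = summarize(frame[~frame["is_weekend"]])
    weekend_mean, weekend_min = summarize(frame[frame["is_weekend"]])
    return WeeklySplit(weekday_mean, weekend_mean, weekday_min, weekend_min)


def participant_profile(
    measurements,
    usual_gait_speed: float | None = None,
    *,
    min_wear_days: int = DEFAULT_MIN_WEAR_DAYS,
    bin_edges: Sequence[int] | None = None,
) -> ParticipantGaitProfile:
    """Assemble the full per-participant gait profile.

    Mean, median and SD (sample SD; 0 when fewer than two measurements) are
    computed over all measurements, not over daily means.  ``eligible`` is
    true when the number of distinct wear-days reaches ``min_wear_days``.
    The percentile-vs-usual fields are ``None`` when no usual gait speed is
    supplied.
    """
    if min_wear_days < 1:
        raise ParameterError("min_wear_days must be >= 1")
    frame = _frame(measurements)
    pids = frame["participant_id"].unique()
    if len(pids) != 1:
        raise ValidationError(f"expected one participant, got {sorted(map(str, pids))}")
    speeds = frame["speed"].to_numpy()
    mean = float(speeds.mean())
    sd = float(speeds.std(ddof=1)) if speeds.size > 1 else 0.0
    dow_profile = {}
    for index, name in enumerate(_DAY_NAMES):
        sub = frame[frame["dow"] == index]
        dow_profile[name] = float(sub["speed"].mean()) if len(sub) else None
    split = weekly_split(frame)
    if usual_gait_speed is not None:
        ratio = percentile_vs_usual(frame, usual_gait_speed)
        percentile, faster, slower = ratio.percentile, ratio.pct_faster25, ratio.pct_slower25
    else:
        percentile = faster = slower = None
    wear_days = int(frame["date"].nunique())
    return ParticipantGaitProfile(
        participant_id=str(pids[0]),
        n_measurements=int(len(frame)),
        mean_speed=mean,
        median_speed=float(np.median(speeds)),
        sd_speed=sd,
        cv_pct=100.0 * sd / mean,
        hourly_profile=diurnal_profile(frame, bin_edges),
        dow_profile=dow_profile,
        weekday_mean=split.weekday_mean,
        weekend_mean=split.weekend_mean,
        weekday_walk_min=split.weekday_walk_min,
        weekend_walk_min=split.weekend_walk_min,
        percentile_vs_usual=percentile,
        pct_faster25=faster,
        pct_slower25=slower,
        wear_days=wear_days,
        eligible=wear_days >= min_wear_days,
    )
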