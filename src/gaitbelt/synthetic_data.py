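"""Synthetic walking signals and cohorts with known ground truth.

Two layers of simulation make the whole measurement chain testable without
any real recordings:

*Signal level* — :func:`simulate_walk_signal` produces a triaxial
accelerometer trace whose vertical axis is a phase-locked two-harmonic
cosine around the 1 g gravity baseline:

    z(t) = 1 - A cos(2 pi c t) + f A cos(4 pi c t) + noise

With the second harmonic phase-locked this way, the analytic maxima of the
noiseless signal stay exactly at ``t = (k + 1/2) / c`` for any harmonic
fraction ``f < 1/4`` (beyond 1/4 a secondary maximum appears between
steps, so the spec rejects it).  Those maxima are returned as the true
step times, giving peak detection an exact oracle.  This is a test signal,
not a biomechanical model.

*Cohort level* — :func:`simulate_cohort` draws participant attributes from
group-specific normal distributions whose defaults reproduce the published
contrast between sarcopenic and normal older men (daily-life speed
1.12 (0.11) vs 1.23 (0.08) m/s, grip 27.4 (5.4) vs 37.2 (5.8) kg, ASM index
6.39 (0.34) vs 6.79 (0.77) kg/m^2, usual speed 0.97 (0.12) vs 1.28 (0.16)
m/s, ages 76.0 (6.2) vs 70.5 (7.6) y), with group sizes 13 / 93.
Sarcopenic members are rejection-sampled to satisfy the AWGS rule by
construction, normal members to fail it.  Each participant's measurement
stream carries a diurnal modulation peaking in the 5-7 h bin, a small
weekday speed surplus, and within-person noise.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math

import numpy as np

from .data_io import AccelerometerRecording, ParticipantProfile
from .exceptions import AliasingError, ParameterError, RejectionBudgetError
from .gait_speed import GaitSpeedMeasurement
from .sarcopenia import AwgsCutoffs

#: Waking window within which bouts are drawn, hours of the local day.
DEFAULT_WAKING_HOURS = (5.0, 23.0)

#: A Monday, so weekday/weekend structure is aligned with calendar weeks.
DEFAULT_START_DATE = dt.date(2019, 1, 7)


# ---------------------------------------------------------------------------
# signal level
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class WalkSignalSpec:
    """Parameters of one simulated walking signal.

    cadence is in steps/s (must lie in the physiological band (0.5, 4)),
    amplitudes and noise in g.  ``sampling_rate`` must be at least four
    times the cadence so peaks are resolvable.
    """

    cadence: float = 1.8
    duration: float = 60.0
    sampling_rate: float = 50.0
    peak_amplitude: float = 0.5
    harmonic_fraction: float = 0.2
    noise_sd: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.cadence < 4.0:
            raise ParameterError(f"cadence {self.cadence} outside (0.5, 4) steps/s")
        if self.sampling_rate < 4.0 * self.cadence:
            raise AliasingError(
                f"sampling_rate {self.sampling_rate} < 4 x cadence {self.cadence}"
            )
        if self.duration <= 0 or self.peak_amplitude <= 0:
            raise ParameterError("duration and peak_amplitude must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0.0 <= self.harmonic_fraction < 0.25:
            raise ParameterError(
                "harmonic_fraction must lie in [0, 0.25): beyond 1/4 the "
                "second harmonic creates spurious peaks between steps"
            )


def true_step_times(spec: WalkSignalSpec) -> np.ndarray:
    """Analytic maxima of the noiseless signal: ``(k + 1/2) / cadence < duration``."""
    n = int(math.ceil(spec.cadence * spec.duration - 0.5))
    return (np.arange(n) + 0.5) / spec.cadence


def simulate_walk_signal(
    spec: WalkSignalSpec,
    participant_id: str = "sim-walk",
    start_time: dt.datetime = dt.datetime(2019, 1, 7, 9, 0),
) -> tuple[AccelerometerRecording, np.ndarray]:
    """Simulate a walking recording; returns ``(recording, true_step_times)``.

    The vertical axis carries the walking waveform plus Gaussian noise of
    SD ``noise_sd``; the two horizontal axes carry smaller noise (half the
    SD).  Identical spec and seed give bit-identical recordings.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    theta = 2.0 * np.pi * spec.cadence * t
    z = (
        1.0
        - spec.peak_amplitude * np.cos(theta)
        + spec.harmonic_fraction * spec.peak_amplitude * np.cos(2.0 * theta)
    )
    x = rng.normal(0.0, 0.5 * spec.noise_sd, n)
    y = rng.normal(0.0, 0.5 * spec.noise_sd, n)
    z = z + rng.normal(0.0, spec.noise_sd, n)
    recording = AccelerometerRecording(
        participant_id=participant_id,
        sampling_rate=spec.sampling_rate,
        start_time=start_time,
        samples=np.column_stack([x, y, z]),
    )
    return recording, true_step_times(spec)


# ---------------------------------------------------------------------------
# measurement-stream level
# ---------------------------------------------------------------------------

def _diurnal_shape(hour: np.ndarray) -> np.ndarray:
    """Unit-amplitude diurnal modulation peaking at 06:00 (the 5-7 h bin)."""
    return np.cos(2.0 * np.pi * (hour - 6.0) / 24.0)


def simulate_participant_days(
    participant_id: str,
    base_speed: float,
    days: int = 28,
    *,
    diurnal_amplitude: float = 0.05,
    weekday_effect: float = 0.01,
    noise_sd: float = 0.24,
    measurements_per_day: float = 73.0,
    start_date: dt.date = DEFAULT_START_DATE,
    waking_hours: tuple[float, float] = DEFAULT_WAKING_HOURS,
    bout_duration_shape: float = 4.0,
    bout_duration_scale: float = 18.08,
    cadence: float = 1.8,
    min_speed: float = 0.3,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[list[GaitSpeedMeasurement], dict]:
    """Simulate a multi-day stream of bout-level gait speed measurements.

    Per day the bout count is Poisson(``measurements_per_day``); bout start
    times are uniform within the waking window.  Bout speed is

        base + diurnal_amplitude * g(hour) + weekday_effect * 1[weekday] + noise

    with ``g`` peaking at 06:00, Gaussian noise of SD ``noise_sd``
    truncated (by redrawing) so speeds stay above ``min_speed``.  Bout
    durations are Gamma distributed; defaults give a mean of 72.3 s so that
    73 bouts/day accumulate about 88 minutes of daily walking.  Returns the
    measurements plus a ground-truth parameter record.
    """
    if days < 1:
        raise ParameterError("days must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    w_lo, w_hi = waking_hours
    measurements: list[GaitSpeedMeasurement] = []
    counts = rng.poisson(measurements_per_day, days)
    for day_index in range(days):
        n = int(counts[day_index])
        if n == 0:
            continue
        date = start_date + dt.timedelta(days=day_index)
        is_weekday = date.weekday() < 5
        hours = np.sort(rng.uniform(w_lo, w_hi, n))
        loc = (
            base_speed
            + diurnal_amplitude * _diurnal_shape(hours)
            + (weekday_effect if is_weekday else 0.0)
        )
        speeds = loc + rng.normal(0.0, noise_sd, n)
        bad = speeds <= min_speed
        while bad.any():  # truncation by redraw, never clamping
            speeds[bad] = loc[bad] + rng.normal(0.0, noise_sd, int(bad.sum()))
            bad = speeds <= min_speed
        durations = rng.gamma(bout_duration_shape, bout_duration_scale, n)
        midnight = dt.datetime.combine(date, dt.time())
        for k in range(n):
            duration = float(durations[k])
            measurements.append(
                GaitSpeedMeasurement(
                    participant_id=participant_id,
                    timestamp=midnight + dt.timedelta(hours=float(hours[k])),
                    speed=float(speeds[k]),
                    duration=duration,
                    n_steps=max(2, int(round(duration * cadence))),
                )
            )
    truth = {
        "participant_id": participant_id,
        "base_speed": base_speed,
        "diurnal_amplitude": diurnal_amplitude,
        "weekday_effect": weekday_effect,
        "noise_sd": noise_sd,
        "measurements_per_day": measurements_per_day,
        "days": days,
    }
    return measurements, truth


# ---------------------------------------------------------------------------
# cohort level
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GroupParams:
    """Marginal (mean, SD) attribute distributions for one cohort group.

    Attributes are drawn as independent truncated normals; the published
    tables provide marginals only, so no within-person correlation is
    imposed.
    """

    speed: tuple[float, float]
    usual: tuple[float, float]
    grip: tuple[float, float]
    asmi: tuple[float, float]
    age: tuple[float, float]
    bmi: tuple[float, float]
    height: tuple[float, float]
    hypertension: float
    diabetes: float
    angina: float
    arthritis: float
    smoking: tuple[float, float, float]  # current, ex, never

    def __post_init__(self) -> None:
        for name in ("speed", "usual", "grip", "asmi", "age", "bmi", "height"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ParameterError(f"{name} SD must be >= 0, got {sd}")
        total = sum(self.smoking)
        self.smoking = tuple(p / total for p in self.smoking)


def sarcopenic_defaults() -> GroupParams:
    return GroupParams(
        speed=(1.12, 0.11), usual=(0.97, 0.12), grip=(27.4, 5.4),
        asmi=(6.39, 0.34), age=(76.0, 6.2), bmi=(25.0, 2.5), height=(1.68, 0.06),
        hypertension=0.846, diabetes=0.231, angina=0.462, arthritis=0.154,
        smoking=(0.462, 0.462, 0.077),
    )


def normal_defaults() -> GroupParams:
    return GroupParams(
        speed=(1.23, 0.08), usual=(1.28, 0.16), grip=(37.2, 5.8),
        asmi=(6.79, 0.77), age=(70.5, 7.6), bmi=(24.5, 2.5), height=(1.68, 0.06),
        hypertension=0.602, diabetes=0.269, angina=0.172, arthritis=0.172,
        smoking=(0.108, 0.753, 0.140),
    )


@dataclasses.dataclass
class CohortSpec:
    """Full specification of a simulated two-group cohort.

    Defaults reproduce the published group structure: 13 sarcopenic and 93
    normal participants observed for 28 days at about 73 bouts/day.
    """

    n_sarcopenic: int = 13
    n_normal: int = 93
    sarcopenic: GroupParams = dataclasses.field(default_factory=sarcopenic_defaults)
    normal: GroupParams = dataclasses.field(default_factory=normal_defaults)
    diurnal_amplitude: float = 0.05
    weekday_effect: float = 0.01
    within_noise_sd: float = 0.24
    measurements_per_day: float = 73.0
    days: int = 28
    start_date: dt.date = DEFAULT_START_DATE
    grip_trial_sd: float = 1.0
    rejection_budget: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sarcopenic < 0 or self.n_normal < 0:
            raise ParameterError("group sizes must be >= 0")
        if self.days < 1:
            raise ParameterError("days must be >= 1")


@dataclasses.dataclass
class CohortResult:
    profiles: list[ParticipantProfile]
    measurements: dict[str, list[GaitSpeedMeasurement]]
    truth: dict

    @property
    def all_measurements(self) -> list[GaitSpeedMeasurement]:
        out: list[GaitSpeedMeasurement] = []
        for pid in self.measurements:
            out.extend(self.measurements[pid])
        return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float = np.inf,
    budget: int = 1000,
) -> float:
    for _ in range(budget):
        value = rng.normal(mean, sd)
        if lo < value < hi:
            return float(value)
    raise RejectionBudgetError(
        f"could not draw N({mean}, {sd}) within ({lo}, {hi}) in {budget} attempts"
    )


def _draw_awgs_components(
    rng: np.random.Generator,
    params: GroupParams,
    want_diagnosed: bool,
    trial_sd: float,
    budget: int,
    cutoffs: AwgsCutoffs,
) -> tuple[tuple[float, float, float], float, float]:
    """Rejection-sample (grip trials, usual speed, ASM index) so the AWGS
    diagnosis comes out as requested."""
    for _ in range(budget):
        center = rng.normal(*params.grip)
        trials = center + rng.normal(0.0, trial_sd, 3)
        usual = rng.normal(*params.usual)
        asmi = rng.normal(*params.asmi)
        if center <= 5 or trials.min() <= 0 or usual <= 0.2 or asmi <= 3:
            continue
        grip_mean = float(trials.mean())
        diagnosed = asmi < cutoffs.asm_index_kg_m2 and (
            grip_mean < cutoffs.grip_kg or usual < cutoffs.gait_speed_ms
        )
        if diagnosed == want_diagnosed:
            return tuple(float(v) for v in trials), float(usual), float(asmi)
    raise RejectionBudgetError(
        f"could not draw AWGS components with diagnosis={want_diagnosed} "
        f"in {budget} attempts; the group distributions may be unsatisfiable"
    )


def simulate_cohort(spec: CohortSpec | None = None) -> CohortResult:
    """Simulate participant attributes and measurement streams for a cohort.

    Sarcopenic-group members satisfy the AWGS diagnosis rule by
    construction and normal-group members fail it (rejection sampling with
    ``spec.rejection_budget`` attempts per participant).  The returned
    truth record carries every generator parameter and per-participant
    latent values, including a lower-limb muscle mass derived from ASM.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    cutoffs = AwgsCutoffs()
    profiles: list[ParticipantProfile] = []
    measurements: dict[str, list[GaitSpeedMeasurement]] = {}
    rows = []
    plan = [("sarcopenic", spec.sarcopenic, spec.n_sarcopenic),
            ("normal", spec.normal, spec.n_normal)]
    index = 0
    for group, params, count in plan:
        for _ in range(count):
            index += 1
            pid = f"P{index:03d}"
            height = _truncated_normal(rng, *params.height, lo=1.4, hi=2.1)
            age = _truncated_normal(rng, *params.age, lo=50.0, hi=95.0)
            bmi = _truncated_normal(rng, *params.bmi, lo=14.0, hi=45.0)
            weight = bmi * height**2
            trials, usual, asmi = _draw_awgs_components(
                rng, params, group == "sarcopenic", spec.grip_trial_sd,
                spec.rejection_budget, cutoffs,
            )
            asm = asmi * height**2
            # lower limbs hold roughly 70% of appendicular lean mass
            leg_mass = 0.7 * asm + rng.normal(0.0, 0.4)
            base_speed = _truncated_normal(rng, *params.speed, lo=0.4)
            stream, _ = simulate_participant_days(
                pid, base_speed, spec.days,
                diurnal_amplitude=spec.diurnal_amplitude,
                weekday_effect=spec.weekday_effect,
                noise_sd=spec.within_noise_sd,
                measurements_per_day=spec.measurements_per_day,
                start_date=spec.start_date,
                rng=rng,
            )
            wear_days = len({m.timestamp.date() for m in stream})
            profiles.append(
                ParticipantProfile(
                    participant_id=pid,
                    sex="male",
                    age=age,
                    height=height,
                    weight=weight,
                    handgrip_trials=trials,
                    asm=asm,
                    usual_gait_speed=usual,
                    wear_days=wear_days,
                    hypertension=bool(rng.random() < params.hypertension),
                    diabetes=bool(rng.random() < params.diabetes),
                    angina=bool(rng.random() < params.angina),
                    arthritis=bool(rng.random() < params.arthritis),
                    smoking=["current", "ex", "never"][
                        int(rng.choice(3, p=params.smoking))
                    ],
                )
            )
            measurements[pid] = stream
            rows.append(
                {
                    "participant_id": pid, "group": group,
                    "base_speed": base_speed, "age": age, "height": height,
                    "weight": weight, "asmi": asmi, "asm": asm,
                    "leg_muscle_mass": float(leg_mass),
                    "grip_mean": float(np.mean(trials)), "usual": usual,
                }
            )
    truth = {
        "participants": rows,
        "diurnal_amplitude": spec.diurnal_amplitude,
        "weekday_effect": spec.weekday_effect,
        "within_noise_sd": spec.within_noise_sd,
        "group_speed_means": {
            "sarcopenic": spec.sarcopenic.speed[0],
            "normal": spec.normal.speed[0],
        },
    }
    return CohortResult(profiles=profiles, measurements=measurements, truth=truth)
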