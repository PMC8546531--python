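"""AWGS sarcopenia classification and its component measurements.

The Asian Working Group for Sarcopenia rule implemented here diagnoses
sarcopenia when appendicular skeletal muscle (ASM) index is low AND at
least one of muscle strength (handgrip) or physical performance (usual
gait speed) is low.  Default cutoffs are the male AWGS values: grip
< 28 kg, usual gait speed < 1.0 m/s, ASM/height**2 < 7.0 kg/m**2 — all
strict inequalities, so a value exactly at a cutoff is classified normal.
Female cutoffs can be supplied through :class:`AwgsCutoffs`.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

from .data_io import ParticipantProfile
from .exceptions import IncompleteAssessmentError, ParameterError, ValidationError


@dataclasses.dataclass(frozen=True)
class AwgsCutoffs:
    """Diagnostic cutoffs; defaults are the male AWGS values."""

    grip_kg: float = 28.0
    gait_speed_ms: float = 1.0
    asm_index_kg_m2: float = 7.0


@dataclasses.dataclass
class SarcopeniaAssessment:
    participant_id: str
    low_strength: bool
    low_performance: bool
    low_mass: bool
    diagnosis: bool
    grip_mean: float
    asm_index: float
    usual_gait_speed: float


def handgrip_mean(trials: Sequence[float]) -> float:
    """Arithmetic mean of exactly three positive dominant-hand grip trials (kg)."""
    trials = tuple(trials)
    if len(trials) != 3:
        raise ValidationError(f"expected exactly 3 grip trials, got {len(trials)}")
    if any(v <= 0 for v in trials):
        raise ValidationError(f"grip trials must be positive, got {trials}")
    return sum(trials) / 3.0


def usual_gait_speed(elapsed: float, distance: float = 4.5) -> float:
    """Walkway gait speed: timed-section distance over elapsed time, m/s.

    The default 4.5 m corresponds to the timed section of a walkway with
    1-m acceleration and deceleration phases on either side.
    """
    if distance <= 0 or elapsed <= 0:
        raise ParameterError("distance and elapsed time must both be > 0")
    return distance / elapsed


def classify_awgs(
    profile: ParticipantProfile, cutoffs: AwgsCutoffs | None = None
) -> SarcopeniaAssessment:
    """Apply the AWGS rule to a participant profile.

    The grip value is the mean of the three stored trials and the ASM index
    is recomputed from ``asm`` and ``height`` (a file-supplied index is
    never used).  Diagnosis is ``low_mass AND (low_strength OR
    low_performance)``.

    Raises
    ------
    IncompleteAssessmentError
        A component (grip trials, ASM, or usual gait speed) is missing;
        the message names it.
    """
    cutoffs = cutoffs or AwgsCutoffs()
    for field, label in (
        ("handgrip_trials", "handgrip trials"),
        ("asm", "appendicular skeletal muscle mass"),
        ("usual_gait_speed", "usual gait speed"),
    ):
        if getattr(profile, field) is None:
            raise IncompleteAssessmentError(
                f"{profile.participant_id}: missing {label}"
            )
    grip = handgrip_mean(profile.handgrip_trials)
    asm_index = profile.asm_index
    usual = profile.usual_gait_speed
    low_strength = grip < cutoffs.grip_kg
    low_performance = usual < cutoffs.gait_speed_ms
    low_mass = asm_index < cutoffs.asm_index_kg_m2
    return SarcopeniaAssessment(
        participant_id=profile.participant_id,
        low_strength=low_strength,
        low_performance=low_performance,
        low_mass=low_mass,
        diagnosis=low_mass and (low_strength or low_performance),
        grip_mean=grip,
        asm_index=asm_index,
        usual_gait_speed=usual,
    )
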