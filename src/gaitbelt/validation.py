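"""Scoring detected steps against annotated ground truth.

Three metrics summarize detector quality against a reference (e.g. video)
annotation:

* sensitivity — percentage of true steps that were detected,
* positive predictive value (PPV) — percentage of detections that are true,
* step-count consistency — ``100 * (1 - |N_detected - N_true| / N_true)``,
  clamped at 0.

Matching is one-to-one and greedy: true steps are scanned in order and each
is matched to the nearest unmatched detection within a time tolerance
(default 0.3 s, about half a typical step interval).  Whenever true steps
are separated by more than twice the tolerance, each detection is feasible
for at most one true step, so the greedy matching attains the optimal
assignment.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ParameterError, UndefinedMetricError, ValidationError
from .step_detection import DetectionConfig, StepSeries, acceleration_magnitude, detect_steps
from .synthetic_data import WalkSignalSpec, simulate_walk_signal

DEFAULT_TOLERANCE = 0.3


@dataclasses.dataclass
class StepMatchResult:
    tp: int
    fp: int
    fn: int
    consistency: float
    sensitivity: float
    ppv: float
    tolerance: float


def _as_times(steps) -> np.ndarray:
    times = steps.step_times if isinstance(steps, StepSeries) else np.asarray(steps, float)
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValidationError("step times must be strictly increasing")
    return times


def match_steps(
    detected, truth, tolerance: float = DEFAULT_TOLERANCE
) -> StepMatchResult:
    """Match detected steps to annotated true steps within a tolerance.

    True steps are scanned in order; each is matched one-to-one to the
    nearest unmatched detection within ``tolerance`` seconds (ties take the
    earlier detection).  Matched pairs count as true positives, unmatched
    detections as false positives, unmatched true steps as false negatives.

    Raises
    ------
    UndefinedMetricError
        The truth sequence is empty (consistency has no denominator).
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be > 0")
    det = _as_times(detected)
    tru = _as_times(truth)
    if tru.size == 0:
        raise UndefinedMetricError("metrics are undefined for an empty truth sequence")
    matched = np.zeros(det.size, dtype=bool)
    tp = 0
    for t in tru:
        lo = int(np.searchsorted(det, t - tolerance, side="left"))
        hi = int(np.searchsorted(det, t + tolerance, side="right"))
        candidates = [i for i in range(lo, hi) if not matched[i]]
        if not candidates:
            continue
        best = min(candidates, key=lambda i: (abs(det[i] - t), det[i]))
        matched[best] = True
        tp += 1
    n_det, n_tru = int(det.size), int(tru.size)
    fp = n_det - tp
    fn = n_tru - tp
    return StepMatchResult(
        tp=tp,
        fp=fp,
        fn=fn,
        consistency=max(0.0, 100.0 * (1.0 - abs(n_det - n_tru) / n_tru)),
        sensitivity=100.0 * tp / n_tru,
        ppv=100.0 * tp / n_det if n_det else float("nan"),
        tolerance=tolerance,
    )


def evaluate_detector(
    spec_grid: Iterable[WalkSignalSpec],
    config: DetectionConfig | None = None,
    n_replicates: int = 5,
    seed: int = 0,
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """Run simulate -> detect -> match over a grid of signal specs.

    Each grid cell is replicated ``n_replicates`` times with seeds derived
    deterministically from ``seed``; the returned frame holds per-cell mean
    and SD of sensitivity, PPV and consistency.
    """
    rows = []
    for cell_index, spec in enumerate(spec_grid):
        metrics = {"sensitivity": [], "ppv": [], "consistency": []}
        for rep in range(n_replicates):
            child = np.random.SeedSequence([seed, cell_index, rep])
            rep_seed = int(child.generate_state(1)[0] % 2**31)
            rep_spec = dataclasses.replace(spec, seed=rep_seed)
            recording, truth = simulate_walk_signal(rep_spec)
            steps = detect_steps(
                acceleration_magnitude(recording), recording.sampling_rate, config
            )
            result = match_steps(steps, truth, tolerance)
            metrics["sensitivity"].append(result.sensitivity)
            metrics["ppv"].append(result.ppv)
            metrics["consistency"].append(result.consistency)
        row = {
            "cadence": spec.cadence,
            "duration": spec.duration,
            "sampling_rate": spec.sampling_rate,
            "peak_amplitude": spec.peak_amplitude,
            "noise_sd": spec.noise_sd,
        }
        for name, values in metrics.items():
            values = np.asarray(values, dtype=float)
            row[f"{name}_mean"] = float(values.mean())
            row[f"{name}_sd"] = float(values.std(ddof=1)) if values.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
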