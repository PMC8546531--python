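# gaitbelt

Free-living gait speed from a belt-worn triaxial accelerometer, and the
clinical analytics built on top of it: daily-life gait descriptors,
sarcopenia classification, and cohort statistics.

Supervised walkway tests capture a single "usual gait speed" value, but an
older adult's real-world walking speed varies with the time of day, the day
of the week, and their health state.  A wearable accelerometer can produce
thousands of speed measurements per person per month; `gaitbelt` implements
the full measurement chain for that setting, plus a synthetic-data layer so
every stage is testable with exact ground truth and no real recordings.

## The measurement chain

1. **Step detection.**  The gravity-removed acceleration magnitude
   `sqrt(ax² + ay² + az²) − median` is smoothed and its peaks detected with
   a minimum prominence (default 0.05 g) and a minimum separation
   (default 0.25 s, a 4 steps/s cadence ceiling).  Each retained peak is a
   step.
2. **Step intervals.**  The time between consecutive steps is quantized to
   a 0.1-s grid (ties round up; a zero rounds up to 0.1 s).
3. **Speed.**  Step length is a sex-specific constant times height
   (`0.415·h` for men, `0.413·h` for women).  Per-step speed is step length
   over the quantized interval; a *walking bout* — a maximal run of steps
   with no gap above 2.5 s and at least 8 steps — yields one measurement:
   the mean of its per-step speeds, `v = k_sex · h / T̄`.
4. **Daily-life analytics.**  Per-day walking time and mean speed, a
   diurnal profile over twelve 2-h bins, weekday/weekend split, SD and
   coefficient of variation, and each participant's distribution of
   `100 · v / v_usual` summarized by its median ("percentile vs usual") and
   the fractions of measurements >25 % faster or slower than usual.
5. **Sarcopenia (AWGS).**  Diagnosis = low appendicular skeletal muscle
   index (< 7.0 kg/m²) AND (low grip strength (< 28 kg) OR low usual gait
   speed (< 1.0 m/s)); strict inequalities, male cutoffs by default.
6. **Cohort statistics.**  Welch t / ANOVA / chi-square / Fisher group
   comparisons, pairwise-complete Pearson correlation matrices, and OLS
   with standardized β and variance inflation factors.
7. **Validation metrics.**  Detected steps are matched one-to-one to
   annotated steps within ±0.3 s; sensitivity, positive predictive value
   and step-count consistency `100·(1 − |N_d − N_t|/N_t)` are reported.

## Worked example

```python
from gaitbelt import (
    WalkSignalSpec, simulate_walk_signal, acceleration_magnitude,
    detect_steps, measure_recording, match_steps,
)

spec = WalkSignalSpec(cadence=2.0, duration=60.0, sampling_rate=50.0,
                      noise_sd=0.0, seed=1)
recording, truth = simulate_walk_signal(spec)

steps = detect_steps(acceleration_magnitude(recording), 50.0)
print(len(truth), steps.n_steps)          # 120 120

result = match_steps(steps, truth)
print(result.sensitivity, result.ppv)     # 100.0 100.0

(m,) = measure_recording(recording, height=1.70, sex="male")
print(round(m.speed, 4), m.n_steps)       # 1.411 120
```

A 60-s walk at 2 steps/s produces 120 steps, all recovered exactly from the
noise-free signal; with height 1.70 m the bout speed is
`0.415 · 1.70 / 0.5 s = 1.411 m/s` — the step-length constant times height
times cadence.

The same chain is scriptable from the shell:

```sh
gaitbelt simulate cohort --seed 1 --out cohort/
gaitbelt classify  --participants cohort/participants.csv --out assessments.csv
gaitbelt aggregate --measurements cohort/measurements.csv \
                   --participants cohort/participants.csv --out profiles.csv
```

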