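# Methods

## Scope and data model

`gaitbelt` models the measurement chain of a belt-worn consumer
accelerometer that estimates walking speed continuously in daily life, and
the geriatric analytics layered on top (sarcopenia classification, cohort
statistics).  Inputs are plain CSV: a triaxial acceleration trace in units
of g with a known, out-of-band sampling rate; a participant table with
anthropometrics, three handgrip trials, DEXA appendicular skeletal muscle
mass (ASM) and walkway usual gait speed; and optionally annotated step
times for validation.  Timestamps are timezone-naive local time, since all
calendar context (hour of day, day of week) is meant in the wearer's local
clock.  Recordings are assumed gap-free; files with gaps must be split
upstream.

## Step detection

Detection operates on the gravity-removed magnitude
`‖a‖ − median(‖a‖)` rather than a single axis: a belt-worn device has a
stable but unknown orientation, and the magnitude is orientation-invariant.
Median subtraction removes the 1 g gravity baseline without assuming which
axis points down.

Defaults, all configurable through `DetectionConfig`:

| parameter | default | rationale |
|---|---|---|
| smoothing window | 0.15 s moving average | suppresses sample noise; forced to an odd sample count so symmetric peaks are not shifted |
| min peak separation | 0.25 s | cadence ceiling of 4 steps/s for human walking |
| min prominence | 0.05 g | rejects ripple while keeping soft heel strikes |
| band-pass | off (optional 0.5–3 Hz) | the locomotor band, when environmental drift is present |

Candidate peaks are prominence-filtered local maxima; the separation rule
is enforced greedily from the tallest candidate down, with ties broken
toward the earlier peak so results are deterministic.  These parameters are
exposed as configuration rather than claimed to match any specific
commercial device, whose filter design is unpublished.

Step intervals are quantized to a 0.1-s grid because that is the
resolution at which the speed model consumes them.  The rounding rule is
floor(x/0.1 + 0.5): ties such as 0.25 s round up, and an interval that
would round to zero is clamped to 0.1 s (a step interval cannot be zero).
Quantization therefore never moves an interval by more than 0.05 s as long
as raw intervals are at least 0.05 s, which the 0.25-s separation rule
guarantees.

## Speed model

Step length is a sex-specific constant times body height — 0.415 (men) and
0.413 (women), the classical pedometry values — multiplying height in
meters.  The constant yields *step* length (distance per step interval),
not full stride length; both constants are configurable, so a
stride-length convention (double the distance per two-step cycle) can be
expressed by doubling them.

A *walking bout* is a maximal run of steps whose inter-step gaps never
exceed 2.5 s, with at least 8 steps (~4 s of walking); shorter runs are
treated as shuffles or isolated steps and discarded.  One bout yields one
gait speed measurement: the arithmetic mean of per-step speeds
`step_length / quantized_interval`.  With all intervals equal this reduces
exactly to `k_sex · h · cadence`.  The mean (rather than a harmonic or
duration-weighted average) was chosen for transparency; for the nearly
constant intervals of steady walking the alternatives coincide.  Bout
duration is the raw (unquantized) first-to-last step time, so summed bout
durations never exceed the recording duration.

## Daily-life analytics

Per calendar date: unweighted mean speed and summed bout durations
(walking time).  Participant-level mean/median/SD pool all measurements
directly, not daily means, matching how a device maker would pool a
measurement stream; SD is the sample SD (0 when fewer than two
measurements) and CV = 100·SD/mean.

The diurnal profile uses twelve 2-hour bins [1,3), [3,5), …, [23,1) —
chosen so the early-morning window 5–7 h is a single bin — with empty bins
reported as missing, never zero.  Bin edges are configurable integers.
The weekday/weekend split partitions by timestamp; walking minutes are
normalized per observed calendar day within each partition.

"Percentile vs usual" is the median of the per-measurement ratio
`100 · v / v_usual`, with the >25 %-faster/slower fractions counted with
strict inequalities.  The ratio reading (rather than a rank within a
reference distribution) is the only interpretation consistent with values
above 100 being routine; it is a documented interpretation, not an
established convention.

A wear-day is any date with ≥ 1 measurement; eligibility defaults to
≥ 10 wear-days and imposes no minimum daily wear-time.

## Sarcopenia (AWGS)

Grip strength is the mean of exactly three positive dominant-hand trials.
Usual gait speed is the timed-section distance (default 4.5 m) over
elapsed time.  The ASM index is always recomputed as `asm / height²`; a
file-supplied index is ignored.  Diagnosis = low mass AND (low strength OR
low performance), with male cutoffs 7.0 kg/m², 28 kg, 1.0 m/s as strict
inequalities — equality at a cutoff is classified normal, following the
"<" notation of the consensus definition.  Cutoffs live in a frozen config
object so female AWGS values can be supplied.

## Cohort statistics

Two-group continuous comparisons use the Welch t test (robust to the very
unequal group sizes typical of sarcopenia cohorts, e.g. 13 vs 93); three or
more groups use one-way ANOVA.  Discrete variables use Pearson chi-square,
switching to the Fisher exact test for 2×2 tables with any expected count
below 5.  Correlations are pairwise-complete Pearson with two-tailed p
values; regression uses listwise deletion, standardized β = B·sd(x)/sd(y),
and VIF_j = 1/(1−R²_j) from the auxiliary regression of predictor j on the
others.  No multiple-testing correction is applied by default; a Holm
adjustment helper is provided.

## Synthetic data

The signal generator produces a vertical-axis waveform

    z(t) = 1 − A·cos(2πct) + f·A·cos(4πct) + ε,   ε ~ N(0, σ²)

with the two horizontal axes carrying noise at half the SD.  With the
second harmonic phase-locked as cosine, the analytic maxima of the
noiseless waveform remain exactly at `t = (k + ½)/c` for any harmonic
fraction f < ¼ (checked by differentiating: the only critical points with
negative curvature in each cycle sit at θ = π).  Those times are returned
as ground truth, giving the detector an exact oracle.  f ≥ ¼ is rejected
because a secondary maximum then appears between steps.  Defaults:
amplitude 0.5 g, harmonic fraction 0.2, noise 0.05 g, 50 samples/s.  This
is a test harness, not a biomechanical model: real signals have asymmetric
heel-strike transients, drift, and posture changes that it does not
emulate, so perfect zero-noise recovery demonstrates algorithmic
correctness, not field accuracy.

The cohort generator encodes the study conditions of a male outpatient
cohort of 106 (13 sarcopenic / 93 normal) observed for 28 days.  Group
attribute distributions are independent truncated normals with means (SD):

| attribute | sarcopenic | normal |
|---|---|---|
| daily-life speed (m/s) | 1.12 (0.11) | 1.23 (0.08) |
| usual gait speed (m/s) | 0.97 (0.12) | 1.28 (0.16) |
| grip (kg) | 27.4 (5.4) | 37.2 (5.8) |
| ASM index (kg/m²) | 6.39 (0.34) | 6.79 (0.77) |
| age (y) | 76.0 (6.2) | 70.5 (7.6) |
| BMI (kg/m²) | 25.0 (2.5) | 24.5 (2.5) |

Height is not reported in such cohort tables; N(1.68, 0.06) m is used as a
realistic distribution for older Korean men, and weight follows from BMI.
Comorbidity and smoking prevalences follow the group tables.  AWGS
components are rejection-sampled (budget 1000 attempts, then an error) so
group membership and diagnosis agree by construction.  Lower-limb muscle
mass is derived as 70 % of ASM plus noise and carried in the truth record
for regression demonstrations.

Measurement streams: Poisson(73) bouts/day within waking hours
05:00–23:00, Gamma(4, 18.08)-distributed bout durations (mean 72.3 s, so a
default day accumulates ≈ 88 min of walking), and speed

    v = base + 0.05·cos(2π(h−6)/24) + 0.01·1[weekday] + N(0, 0.24),

truncated by redrawing below 0.3 m/s.  The diurnal term peaks at 06:00
(the 5–7 h bin) and the within-person SD of 0.24 m/s reproduces a CV of
roughly 20 %.  Attribute independence is the main simplification: real
grip, mass and speed are correlated within person, so cross-variable
statistics on simulated cohorts are conservative.

## Validation metrics

Greedy in-order matching within ±0.3 s (about half a typical step
interval) was chosen over optimal assignment for transparency; whenever
true steps are separated by more than twice the tolerance each detection
is feasible for at most one true step, so greedy and optimal matching
coincide — the test suite verifies this against an exhaustive assignment
oracle.  Consistency `100·(1 − |N_d − N_t|/N_t)` is clamped at 0 and is an
interpretation of the usual "step-count agreement" phrasing; PPV is
undefined (NaN) when there are no detections.

## Problem sizes and numerical notes

The acceptance script runs four 60-s zero-noise walks, a full-scale cohort
(≈ 2.2 × 10⁵ measurements), 50 scaled-down cohort replicates
(10 days × ~15 bouts/day) for the group-difference rejection rate, 10⁴
random step trains for the quantization bound, and 500 matching-oracle
cases; the statistical test suite uses the same scaled stream sizes with
seeded replicates.  Group-difference testing on pooled measurements treats
bouts as independent, as is conventional for device-measurement streams,
and is the high-power variant; the participant-mean comparison is also
computed and reported.  Floating-point summation makes the mean of n
identical per-step speeds exact only to ~1 ulp, so "exact" speed-algebra
checks are asserted at relative 1e-12.  All generators draw from a single
`numpy` Generator in a fixed order, so identical seeds give bit-identical
outputs.

## Known limitations

- The detector parameters are plausible-physiology defaults, not a
  validated reimplementation of any commercial device's unpublished
  algorithm.
- Pathological gaits (parkinsonian shuffling, orthopedic asymmetry) are
  out of scope; the cadence ceiling and bout thresholds assume broadly
  normal walking.
- The synthetic cohort cannot reproduce published cohort-specific numbers
  that depend on unavailable raw data (exact correlations, p values, or
  video-validated detection percentages); it reproduces the group
  *structure* so that pipeline properties and power are testable.
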