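# Methods

This note documents the models, conventions, and design choices behind
`odisleep`, in the spirit of a statistical-software methods appendix. It
states how quantities are defined and computed; every empirical number it
mentions is produced by the test suite or `scripts/acceptance.py`, not
asserted here.

## Desaturation indices

An index ODI*nb* counts maximal runs of consecutive 1-Hz samples that are
(i) valid, (ii) have a defined baseline, and (iii) sit at or below
baseline − *n* percentage points, provided the run lasts at least 3 s,
normalised per hour of artifact-free recording. Conventions:

- **"n % decrease"** is an absolute drop of *n* saturation percentage
  points (the standard oximetry reading). A relative (fractional) mode
  exists behind the `relative` flag but is not the default.
- **Baseline A** is the mean of all valid samples — one constant per
  night. **Baseline T** at second *t* is the mean of the ⌈0.2·|W|⌉ largest
  valid values in the half-open preceding-minute window W = [t−60, t);
  with fewer than 12 valid samples (the top-20 % count of a full window)
  the baseline is undefined and no event sample may occur there. ODI2 and
  ODI3 use baseline T; the 4-point index exists in both flavours (ODI4T,
  ODI4A).
- **"Minimum of 3 s"** at 1 Hz means at least 3 consecutive qualifying
  samples, with duration counted inclusively (end − start + 1). The
  `strict_gt` flag demands strictly more than 3 s (≥ 4 samples).
- **Event boundaries** are threshold crossings, not returns to baseline,
  and events separated by even one recovered sample are never merged.
- **Denominator**: events are divided by artifact-free (valid) recording
  hours by default; whether artifact-deleted time should count toward the
  recording time is genuinely ambiguous, so a `denominator="total"`
  switch divides by the full recording length instead.

A consequence worth stating plainly: with run-based counting, the event
*count* is not monotone in the threshold. Lowering *n* enlarges the
sub-threshold sample set, which can merge two adjacent runs across a
partially-recovered (or noise-flickering) bridge into one, so ODI2 can
occasionally count fewer events than ODI3 on the same trace even though
every ODI3 event sample also qualifies at n = 2. The monotone quantity is
sub-threshold *time*. On cohort group means the familiar ordering
ODI2 > ODI3 > ODI4T holds statistically, and the acceptance script checks
the severity gradient at that level.

## Artifact rules and exclusions

Two automated rules mask (never delete) samples: any value below 50 %,
and the later sample of any consecutive pair differing by more than 4
percentage points (4 %/s at 1 Hz). Sub-50 dropouts are treated as missing
before the slew check, so a dropout does not contaminate its neighbours;
a genuine fast swing, by contrast, flags both the swing sample and its
recovery sample (each is a > 4-point jump from its predecessor). The flag
pattern is a pure function of the values, making the operation
idempotent. Masking preserves the time axis, keeps event durations
well-defined, and events may not span masked gaps.

The cohort cascade excludes records with total recording time < 3 h,
total sleep time < 1 h, or age outside [20, 85], labelling each record
with the first matching reason in that order. TST < 4 h is a *flag*, not
a removal, so the full cohort and the TST ≥ 4 h sub-cohort derive from
one pass. TST-based decisions use the PSG sleep summary, never the
oximetry trace (oximetry cannot score sleep).

## Severity and reference quantities

AHI = (apneas + hypopneas) / hours of sleep, from pre-scored event lists;
events must last ≥ 10 s and hypopneas must carry a ≥ 4-point
desaturation. Severity bands are left-closed: normal < 5, mild 5–<15,
moderate 15–<30, severe ≥ 30 events/h — the boundary values 5/15/30 map
upward, matching the convention under which cohort tables are partitioned.

## Synthetic cohort generator

The generator defines the study conditions for all simulation-based
tests. A cohort spec fixes the severity mix (defaults 11.7 / 20.6 / 21.4 /
46.3 % — a tertiary referral population heavily enriched for severe OSA),
per-severity (mean, SD) for age, BMI, neck circumference, Epworth score,
AHI, heart rate, TST, sleep latency and arousal index, and per-group
female fractions. Draws are normal, truncated to physical ranges (age
[20, 85], ESS [0, 24], BMI ≥ 10, NC ≥ 20); AHI draws are resampled until
they fall inside the severity band, so labels and AHI are always
consistent. Group sizes follow largest-remainder rounding (ties toward
the earlier group), which reproduces the 72/127/132/285 split at
n = 616 exactly. Per-severity AHI parameters (2.4 ± 1.5, 9.6 ± 2.9,
21.5 ± 4.3, 52 ± 22 events/h) are the package's own choice, set once so
the cohort-wide mean sits near the mid-30s typical of such referral
populations. AHI is additionally capped at 80 events/h: non-overlapping
10–60 s events with 5-s recovery gaps pack at most ~90/h of sleep, and
the cap keeps every generated patient physically renderable with
headroom. One global seed feeds a per-patient seed (seed + index), so
cohorts are reproducible patient-by-patient; event lists and traces use
fixed offsets of the per-patient seed as independent sub-streams.

**Event planting.** The event count is forced to round(AHI × TST).
Durations are uniform on [10, 60] s. Depths follow a two-component
mixture: 85 % uniform on (6, 13) points — typical of scored
desaturations, and detectable even against an all-night-mean baseline
that the events themselves depress — and 15 % uniform on (2, 4), visible
only to the 2- and 3-point indices. Events deeper than 4 points are
labelled apnea or hypopnea at random; shallow ones are apneas (a
hypopnea requires a ≥ 4-point desaturation by definition). Onsets are
uniform over the sleep period conditional on no overlap: the free time
left after durations and minimum 5-s gaps is split by a flat Dirichlet,
which is the exact conditional distribution and cannot dead-loop at high
densities; an infeasible request raises an error naming the limiting
rate.

**Trace rendering.** The clean signal is a per-patient resting level
(uniform 96–98 %) minus the combined event depression; each event
descends linearly over the first 30 % of its duration, holds a plateau at
full depth, and re-saturates exponentially (τ = 5 s) after it ends, with
overlaps combining by the deeper depression. The instrument model then
applies a beat-windowed exponential moving average: 4 beats at pulse
≤ 112 bpm, 8 beats up to 225, 16 above, converted to seconds through the
instantaneous pulse rate, with per-sample smoothing constant
α = 1 − exp(−Δt/window). "Four-beat exponential averaging"
underdetermines α; this convention makes a step input reach the 1 − 1/e
level exactly one window after the step, which the tests verify in
closed form. The pulse series defaults to a constant 72 bpm (a typical
clinic mean heart rate). Gaussian noise (SD 0.35 points) is added after
averaging, then two artifact classes are injected at Poisson hourly
rates: single-sample downward spikes of 6–12 points (kept above the 50 %
floor, spaced ≥ 3 s apart so each sits between clean samples) and 1–5 s
dropout runs below 50 %.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sleep-stage architecture and REM-dependent
clustering of events; central vs. obstructive event physiology;
between-patient variability in desaturation propensity (depth is drawn
independently of severity); baseline drift, periodic breathing, and
motion artifacts beyond the two modelled classes. Because planted events
map almost one-to-one onto detectable desaturations, the synthetic
ODI–AHI coupling is tighter than biology: classifiers reach near-perfect
cross-validated accuracy on synthetic cohorts, which should be read as a
correctness check of the pipeline, not as a clinical performance
estimate. The simulation quantities the acceptance script reports
(Spearman ODI4A↔AHI, R², Bland–Altman width) land in the same range as
published clinical values, but the classification accuracies do not
transfer.

## Classifiers

Cutoff rules classify positive when the index value is at or above the
cutoff (the boundary is inclusive, matching the ≥-style severity bands).
Published clinic-derived cutoffs for both tasks and both cohorts ship as
defaults. ROC-optimised cutoffs maximise Youden's J = sensitivity +
specificity − 1 over midpoints between adjacent sorted unique scores,
breaking ties toward the higher-specificity (higher) cutoff; identical
scores raise a non-discriminative error. Youden's J is the package's
reading of "best discriminating cutoff" and is deliberately swappable.

SVMs (linear, second-degree polynomial, RBF) run inside a stratified
tenfold cross-validation: features are standardised by training-fold
statistics only, hyperparameters (C ∈ {0.1, 1, 10, 100}, γ ∈ {0.01, 0.1,
1}) are chosen by an inner grid search on the training fold, and
out-of-fold predictions are pooled. The four-class problem uses
one-vs-one voting with decision-value tie-breaking. Fold assignment is a
deterministic function of labels and seed.

## Evaluation statistics

- Confusion metrics: overall accuracy, per-class sensitivity,
  cell-wise misclassification rates; for binary tasks specificity is the
  negative class's sensitivity. A zero row yields an undefined (NaN)
  sensitivity rather than an error.
- ROC/AUC: trapezoidal integration over all unique thresholds, which with
  half-credit tie handling equals the Mann–Whitney concordance
  probability; the tests verify the identity against an O(n²) oracle.
- Bland–Altman: bias = mean(reference − estimate), limits = bias ±
  1.96 × sample (n−1) SD of the differences. Applied after OLS
  calibration the bias is zero by construction.
- Chi-square: Pearson statistic without continuity correction (the
  published gender-by-severity statistic is reproduced only without it).
- Summary ANOVA: the one-way F is reconstructed exactly from (n, mean,
  sample SD) triples — between-SS from means, within-SS from
  (n−1)-weighted variances — and equals the raw-data F whenever the
  summaries used sample SDs.
- Post-hoc orderings: pairwise comparisons reported as "(i) < (j)" pairs.
  The default is **Games-Howell** (Welch degrees of freedom, studentized
  range), because severity groups of desaturation indices are grossly
  heteroscedastic — the severe group's SD is an order of magnitude above
  the normal group's — and a pooled-variance procedure such as Scheffé
  then has essentially no power for comparisons among the milder groups
  and cannot reproduce the published full ordering. Scheffé remains
  available (`method="scheffe"`) and is strictly more conservative here.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 30–616 patients and recordings of
10 minutes to ~6 hours; the detection oracle-equivalence battery runs 200
random traces of ≤ 600 s against a brute-force scanner; parameter
recovery uses 100-patient cohorts at 20 seeds. The moving baseline is
computed vectorially (sliding window sort with missing values pushed to
the end); ties in the top-20 % selection are resolved by value, which is
all the mean requires. All tolerances in tests are either exact
(count-based constructions), 1e-9 (algebraic identities), or explicitly
stated statistical margins.

## Known limitations

- The run-count non-monotonicity across thresholds described above is
  inherent to the event definition; one acceptance-level property test
  asserts the idealised per-trace monotonicity and fails by design on a
  documented counterexample.
- ODI4A compresses at high severity because dense events depress the
  all-night mean; this mirrors reality but means ODI4A is not an unbiased
  AHI estimate without calibration.
- The generator's independence assumptions (depth ⟂ severity, no
  night-to-night variability) make synthetic classification tasks easier
  than clinical ones; see the generator section.
- EDF input is out of scope; traces are CSV (an external EDF reader can
  be adapted upstream of `SpO2Trace.from_frame`).
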