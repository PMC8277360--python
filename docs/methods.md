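# Methods

This note documents the models, conventions, calibration, and numerical
choices behind `gazemetrics`, and what its synthetic benchmarks do and do not
demonstrate.

## Event classification (I-VT with a microfixation tier)

Gaze streams are sequences of tracker samples `(t_ms, x_px, y_px, valid)` at
a nominal rate (default 30 Hz; all arithmetic uses actual timestamps, never
the nominal rate). Each inter-sample interval is labeled independently and
maximal equal-label runs are merged:

- **off-screen** — either endpoint invalid (track loss, gaze off the monitor);
- **saccade** — two-point angular velocity strictly above the threshold
  (default 30 °/s);
- otherwise a sub-threshold run, labeled **fixation** when the run lasts
  strictly more than the minimum duration (default 60 ms) and
  **microfixation** otherwise.

Angular velocity uses the exact tangent conversion
`θ = 2·atan(d·pitch / 2D)` with `pitch = width_cm/width_px` and viewing
distance `D` (default 65 cm). Boundary conventions: exactly at the velocity
threshold is non-saccadic; a sub-threshold run of exactly the minimum
duration is a microfixation. No smoothing or vendor-style noise filter is
applied before thresholding — at ~30 Hz a multi-point velocity estimator is
under-determined, and the two-point estimator is isolated behind
`angular_velocity` as a seam. Fixations are never merged across an
intervening saccade or gap (no glissade repair). Fixation centroids are
unweighted means of member-sample coordinates; saccade `path_length_px` is
the within-event polyline length.

The classifier is deterministic and conservative by construction: event
durations tile `[first sample, last sample]` exactly, and a brute-force
reference (label every interval, then merge) is maintained in the test suite
as an independent oracle.

## Per-participant metrics and the Gaze Index

**Screen time** is fixation + microfixation + saccade time; off-screen
episodes are excluded. Microfixations count as screen time (they are
on-screen by definition). All "per minute" rates divide by screen time;
the alternative normalization of saccade distance per minute of *saccadic*
time is emitted as an extra column (`saccade_px_per_saccade_min`).

The **Gaze Index** is

    GI = Σ fixation time / (Σ saccade time + Σ microfixation time),

i.e. staring over scanning, where scanning includes the short dwells of
reading chains. Because both sides are portions of screen time, GI is
invariant to how long a participant watched the screen (tested as exact
self-concatenation invariance). GI is undefined — an error, not infinity —
when scanning time is zero. Categories: GI < 1 superscanner, 1 ≤ GI < 3
scanner, 3 ≤ GI ≤ 5 starer, GI > 5 superstarer; GI = 3 exactly is a
measure-zero tie binned with starers.

`mean_interfixation_px` averages distances between successive full-fixation
centroids, skipping microfixations; pairs separated by an off-screen episode
are not counted, since gaze relocates unobserved across such a gap.
Undefined quantities (no screen time, < 2 full fixations, zero scan time)
are NaN so cohort tables stay rectangular.

## Cohort statistics

Two-group comparisons use the two-sided Mann-Whitney U test with
`U = min(U₁, U₂)` (the convention consistent with reported U values below
the null mean `n₁n₂/2`). The exact-enumeration path is used for pooled
samples ≤ 16 without ties, otherwise the normal approximation with tie and
continuity corrections; both paths are exposed. Normality is assessed by a
Kolmogorov-Smirnov statistic against a normal with moment-estimated
parameters; since parameters are estimated, the p value comes from a seeded
Lilliefors-style Monte Carlo (default 10⁴ replicates, vectorized). Odds
ratios use `ad/bc` with Haldane–Anscombe +0.5 correction when a cell is
zero and a Woolf log-normal 95% CI; in the cohort panel they contrast being
a superstarer (GI > 5, male vs female) and a superscanner (GI < 1, female
vs male). A toy cohort can leave a GI-extreme bin empty on both sides; the
panel then reports the counts with a NaN odds ratio instead of failing.
No multiple-testing correction is applied by default; a Holm-adjusted
column is opt-in.

## Synthetic gaze streams

The generator emulates 10-minute chart-review recordings at 30 Hz as an
alternating renewal process per participant:

    fixation → saccade (→ microfixation → saccade)* [→ off-screen episode]

- Fixation durations are shifted gamma: two sample intervals (the minimum a
  velocity classifier can resolve at the sampling rate) plus a gamma draw
  with shape 4 (the conventional shape for fixation-duration
  distributions; only the mean is calibrated, the shape is a documented
  free parameter).
- Each scan chain holds a geometric number of saccades whose mean is solved
  in closed form from the target saccade rate per screen-minute; saccade
  durations are one interval plus an exponential remainder; every
  microfixation is exactly one sample interval (33.3 ms at 30 Hz — the only
  lattice duration below 60 ms).
- Saccades travel in straight lines at constant angular speed. Directions
  are drawn uniformly but rejection-sampled so the whole path stays on
  screen; folding a step at the screen edge can shorten the inter-sample
  chord below the velocity threshold and split the saccade, so reflection
  is only a fallback. Curvature would matter only for path length, which
  the speed parameter absorbs.
- Within-fixation jitter is Gaussian (σ 0.8 px) hard-clipped at ±2 px, so
  stare-bout velocity can never approach the threshold (≈ 5 °/s worst
  case), while the smallest saccade step stays safely above it.
- Off-screen episodes (looks at paper notes) follow each cycle with a fixed
  probability — a Poisson process of consultation episodes with mean 5 s —
  tuned to the profile's target on-screen fraction.

All durations are drawn continuously and *stochastically rounded* onto the
sample-interval lattice (floor plus Bernoulli carry). This is
mean-preserving and makes classification recover the generative schedule
without boundary bias, so calibrated means survive the full
generate → classify → measure loop.

### Calibration of the default profiles

`default_profiles()` encodes two behavioral phenotypes whose analytic
expectations under the generator equal the target group means:

| quantity | female | male |
|---|---|---|
| mean fixation duration (ms) | 197.6 | 226.0 |
| saccades per screen-minute | 347 | 288 |
| mean saccade duration (ms) | 63.1 | 56.4 |
| saccade px per screen-minute | 35,026 | 33,542 |
| on-screen fraction of task time | 0.447 | 0.551 |

The within-saccade angular speed is solved from the distance target given
the geometry (one fewer free knob than an independent amplitude), and the
scan-chain mean from the rate target.

**These targets are over-determined with the group-mean Gaze Index values
(2.4 / 3.4) sometimes quoted alongside them.** Saccadic time per
screen-minute is rate × duration = 21.9 s (female) and 16.2 s (male), but a
GI of 2.4 / 3.4 leaves a total scanning budget of only 60/(1+GI) = 17.6 s /
13.6 s — less than the saccade time alone, before any microfixation time.
No event-level process can satisfy all of these simultaneously. The
generator therefore prioritizes the directly measured event metrics; the
realized GI expectation is ≈ 1.1 (female) and ≈ 2.0 (male) — lower than
2.4/3.4 but with the sex ordering, the female-dominant superscanner tail,
and the significance of the GI comparison preserved. The same budget
argument shows the quoted fixations-per-minute values (≈ 190) cannot
coexist with the fixation-duration and saccade-rate targets; fixations/min
is not calibrated (realized ≈ 162/177).

### Between-participant dispersion

`CohortSpec.between_participant_cv` (default 0.22) jitters each
participant's fixation-duration mean, saccade-duration mean, saccade rate,
and off/on-screen odds by independent mean-1 lognormal multipliers. The
default is the geometric mean of the cv values implied by the
fixation-duration group SEMs (7.2 ms at n=46 → 0.247; 6.6 ms at n=47 →
0.200). The full printed dispersion panel cannot be matched by any
independent-multiplier model — the saccade-distance SEM is smaller than
what the rate and duration SEMs alone would propagate into their product —
so only the fixation-duration SEMs are treated as calibration constraints
(and verified at 30% tolerance); other dispersions are emergent.

Two convexity biases are corrected numerically at cohort-generation time
(Gauss–Hermite quadrature + Brent root-finding, deterministic):

1. the on-screen fraction is convex in the jittered off/on odds, and
2. the realized saccade rate is convex in the jittered parameters because a
   cycle cannot contain fewer than one relocating saccade.

Without these, cohort means drift ≈ +1% and ≈ +2–4% respectively.

## Determinism and seeding

A single integer seed drives everything. Cohorts derive independent
per-participant substreams via `numpy` `SeedSequence` spawning, so
generation is reproducible and order-independent; identical configuration
and seed give byte-identical output files (no timestamps in the run
manifest for this reason).

## Problem sizes used in the benchmark suite

Parameter-recovery checks use the full default cohort (46 + 47
participants, 10-minute streams at 30 Hz) over 5 fixed seeds; the power
check uses 50 such cohorts; classifier-oracle equivalence uses 1000
randomized streams of up to 200 samples; exact-test equivalence enumerates
every tie-free rank configuration with pooled size ≤ 10.

## Degenerate inputs and tie-breaks

Fewer than two samples cannot be classified (error); an all-invalid stream
is a single off-screen event. Duplicate timestamps in a file are dropped
(first kept); samples flagged valid but out of bounds are demoted to
invalid on read. Jittered profile parameters are floored at their
structural minima (fixation > two sample intervals, saccade duration > one
interval, saccade rate within the screen-time budget); these floors bind
with negligible probability at the default cv.

## Known limitations

- The generator emulates the *statistical event structure* the analysis
  assumes, not real oculomotor physics: no main-sequence
  amplitude–velocity relation, no drift or tremor spectra, no blink
  taxonomy beyond off-screen gaps, no screen-content-driven gaze. Passing
  recovery tests shows the pipeline is unbiased for data with this
  structure; it cannot certify behavior on vendor exports with correlated
  noise or filtered velocity profiles.
- Per-participant event structure is stationary within a recording;
  real physicians presumably alternate reading-heavy and chart-scanning
  segments, which would widen within-participant variance but not move the
  calibrated means.
- Group GI expectations are below the quoted group means for the reasons
  above; analyses that depend only on GI ordering and dispersion are
  unaffected.
- The Mann-Whitney power of the fixation-duration comparison at the
  calibrated effect size and cohort size is ≈ 0.78–0.80; benchmark runs
  demanding ≥ 80% significant replicates sit exactly at this edge.
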