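# gazemetrics

Velocity-threshold gaze event classification, fixation/saccade metrics, the
**Gaze Index**, and calibrated synthetic gaze-stream simulation — a pipeline
for studying how people (here: physicians reviewing an electronic health
record for 10 minutes under an eye tracker) split their visual attention
between *staring* and *scanning*, and for comparing two cohorts (e.g.
female vs male) on the resulting metric suite.

## What it computes

Raw tracker samples `(t_ms, x_px, y_px, valid)` are segmented by an I-VT
classifier: intervals with two-point angular velocity above 30 °/s are
**saccades**; sub-threshold runs longer than 60 ms are **fixations**, shorter
ones **microfixations** (the stationary dwells of reading chains); intervals
touching invalid samples are **off-screen**. Angular velocity uses
`θ = 2·atan(d·pitch/2D)` with the monitor's pixel pitch and the viewing
distance `D` (default 65 cm).

Per participant the suite includes screen-time fraction, fixations and
saccades per screen-minute, mean fixation and saccade durations, distance
between fixations, saccade distance per screen-minute, and the Gaze Index

    GI = Σ fixation time / (Σ saccade time + Σ microfixation time)

— staring over scanning, normalized to screen time by construction
(GI < 1: "superscanner", < 3 "scanner", 3–5 "starer", > 5 "superstarer").
Cohort comparisons use two-sided Mann-Whitney U tests (min-U convention,
exact or corrected-normal path), Kolmogorov-Smirnov normality with a seeded
Monte-Carlo p value, and odds ratios (Haldane-corrected, Woolf CI) at the GI
extremes.

Because raw recordings of this kind are rarely shareable, the package ships
a synthetic gaze-stream generator: an alternating renewal process of stare
bouts, reading-like saccade–microfixation chains, and off-screen episodes,
with two behavioral profiles calibrated so that the classified cohort means
reproduce target group statistics (fixation 197.6/226 ms, 347/288
saccades/min, 63.1/56.4 ms saccade durations, 35,026/33,542 px/min, 44.7%/
55.1% screen time for the female/male profiles). See `docs/methods.md` for
the model, the calibration, and its documented limits.

## Worked example

Simulate the default 46 + 47 cohort, classify, compute metrics, and compare
the groups:

```bash
gazemetrics run-all --out results/demo --seed 7
```

This writes `metrics.csv` (93 rows), `comparison.csv`, `odds_ratios.csv`,
`gi_summary.json`, and a reproducibility manifest. With seed 7 the
comparison panel contains (abridged):

| metric | female mean (SEM) | male mean (SEM) | U | p |
|---|---|---|---|---|
| screen_time_fraction | 0.442 (0.009) | 0.523 (0.009) | 387 | 1.0e-07 |
| mean_fixation_ms | 192.9 (5.4) | 225.1 (7.0) | 665 | .0014 |
| saccades_per_min | 343.4 (10.2) | 287.0 (7.8) | 568 | 8.2e-05 |
| mean_saccade_ms | 64.4 (1.9) | 55.2 (1.9) | 610 | .0003 |
| gaze_index | 1.46 (0.13) | 2.52 (0.16) | 492 | 6.1e-06 |

and the GI summary `{"n": 93, "min": 0.11, "max": 5.01, "mean": 2.0,
"n_lt3": 74, "n_gt3": 19, "n_lt1": 20, "n_gt5": 1}`: the female-profile
group stares less, scans more and faster, and dominates the superscanner
tail (GI < 1 odds ratio 8.6, female vs male) — the behavioral contrast the
two calibrated profiles encode. Identical seed and options give
byte-identical outputs.

The same steps are available programmatically:

```python
from gazemetrics import (CohortSpec, classify_events, compare_cohort,
                         compute_metrics, generate_cohort)

streams, cohort = generate_cohort(CohortSpec(seed=7))
metrics = [compute_metrics(classify_events(s), s) for s in streams]
comparisons, or_rows = compare_cohort(metrics, cohort)
```

Other subcommands: `gazemetrics simulate` (write per-participant stream
files + `cohort.csv`), `classify` (tidy event table), `metrics`, `compare`.

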