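"""Cohort-level nonparametric comparisons.

Two-group tests use the Mann-Whitney U test (two-sided throughout; the
significance level used in reporting is .05).  The U statistic is reported in
the ``min(U1, U2)`` convention.  Normality is assessed with a
Kolmogorov-Smirnov statistic against a normal law with moment-estimated
parameters, with a seeded Monte-Carlo (Lilliefors-style) p value.  Odds
ratios at the Gaze Index extremes use the Haldane-Anscombe +0.5 correction
for zero cells and a Woolf log-normal confidence interval.

No multiple-testing correction is applied by default; a Holm-adjusted column
can be requested as an opt-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import ClassVar, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .io import CohortRecord
from .metrics import ParticipantMetrics

__all__ = [
    "GroupComparison",
    "FourfoldTable",
    "OddsRatioRow",
    "mann_whitney_u",
    "ks_normality",
    "odds_ratio",
    "compare_cohort",
    "COMPARISON_METRICS",
]

#: metric columns compared between groups, in output order
COMPARISON_METRICS = (
    "screen_time_fraction",
    "fixations_per_min",
    "mean_fixation_ms",
    "mean_interfixation_px",
    "saccade_px_per_min",
    "saccades_per_min",
    "mean_saccade_ms",
    "gaze_index",
)


@dataclass(frozen=True)
class GroupComparison:
    """One metric's two-group comparison (group a = female, group b = male)."""

    metric_name: str
    n_a: int
    n_b: int
    mean_a: float
    dispersion_a: float  # SEM of the per-participant values
    mean_b: float
    dispersion_b: float
    u_statistic: float
    p_value: float
    p_holm: float | None = None

    _csv_optional: ClassVar[tuple] = ("p_holm",)
    _csv_rename: ClassVar[dict] = {
        "metric_name": "metric",
        "n_a": "n_female",
        "n_b": "n_male",
        "mean_a": "mean_female",
        "mean_b": "mean_male",
        "dispersion_a": "sem_female",
        "dispersion_b": "sem_male",
        "u_statistic": "U",
        "p_value": "p",
    }


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 exposure-by-outcome counts: a,b = exposed with/without outcome; c,d = unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("fourfold table must contain at least one count")


@dataclass(frozen=True)
class OddsRatioRow:
    """One odds-ratio contrast with its fourfold counts and 95% CI."""

    contrast: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float

    _csv_rename: ClassVar[dict] = {"odds_ratio": "or"}


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], *, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, U reported as min(U1, U2).

    ``method='auto'`` uses exact enumeration when the pooled sample is small
    (n1+n2 <= 16) and tie-free, otherwise the normal approximation with tie
    and continuity corrections.  ``'exact'`` / ``'asymptotic'`` force a path.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        scipy_method = "exact" if (pooled.size <= 16 and not has_ties) else "asymptotic"
    elif method in ("exact", "asymptotic"):
        scipy_method = method
    else:
        raise ValueError(f"unknown method {method!r}")
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=scipy_method, use_continuity=True
    )
    u1 = float(res.statistic)
    u = min(u1, x.size * y.size - u1)
    return u, float(res.pvalue)


def _ks_stat_sorted(sorted_rows: np.ndarray) -> np.ndarray:
    """KS distance of each (sorted) row against a normal with that row's moments."""
    n = sorted_rows.shape[-1]
    m = sorted_rows.mean(axis=-1, keepdims=True)
    s = sorted_rows.std(axis=-1, ddof=1, keepdims=True)
    u = scipy.stats.norm.cdf((sorted_rows - m) / s)
    i = np.arange(1, n + 1)
    d_plus = (i / n - u).max(axis=-1)
    d_minus = (u - (i - 1) / n).max(axis=-1)
    return np.maximum(d_plus, d_minus)


def ks_normality(
    x: Sequence[float], *, n_sim: int = 10_000, seed=None
) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of normality with moment-estimated parameters.

    Because the null parameters are estimated from the data, the p value is
    obtained by seeded Monte-Carlo resampling (Lilliefors-style): ``n_sim``
    standard-normal samples of the same size, each standardized by its own
    moments.  D is invariant under affine transforms of ``x``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    if x.size < 4:
        raise InputError("normality assessment requires n >= 4")
    if x[0] == x[-1]:
        raise InputError("constant vector: normality test undefined")
    if n_sim < 1:
        raise ValueError("n_sim must be positive")
    d = float(_ks_stat_sorted(x))
    rng = np.random.default_rng(seed)
    sims = np.sort(rng.standard_normal((n_sim, x.size)), axis=1)
    d_sim = _ks_stat_sorted(sims)
    p = (1.0 + (d_sim >= d).sum()) / (n_sim + 1.0)
    return d, float(p)


def odds_ratio(t: FourfoldTable) -> tuple[float, tuple[float, float]]:
    """Odds ratio ad/bc with Haldane-Anscombe +0.5 zero-cell correction and Woolf 95% CI."""
    if (t.a + t.b == 0) or (t.c + t.d == 0) or (t.a + t.c == 0) or (t.b + t.d == 0):
        raise ValueError("fourfold table has an all-zero margin; odds ratio undefined")
    a, b, c, d = (float(v) for v in (t.a, t.b, t.c, t.d))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(orr) - 1.959963984540054 * se)
    hi = math.exp(math.log(orr) + 1.959963984540054 * se)
    return orr, (lo, hi)


def _group_values(
    rows: list[ParticipantMetrics], metric: str
) -> np.ndarray:
    vals = np.array([getattr(r, metric) for r in rows], dtype=float)
    return vals[np.isfinite(vals)]


def compare_cohort(
    metrics: Sequence[ParticipantMetrics],
    cohort: Sequence[CohortRecord],
    *,
    metric_names: Sequence[str] = COMPARISON_METRICS,
    include_performance: bool | None = None,
    holm: bool = False,
    mw_method: str = "auto",
) -> tuple[list[GroupComparison], list[OddsRatioRow]]:
    """Full female-vs-male comparison panel plus odds ratios at the GI extremes.

    Returns one :class:`GroupComparison` per metric (group a = female,
    b = male; NaN values are dropped per metric) and two
    :class:`OddsRatioRow` entries: being male vs female for GI > 5
    ("superstarer") and being female vs male for GI < 1 ("superscanner").

    ``include_performance`` adds ``performance_pct`` as a compared covariate;
    by default it is included when every cohort record carries it.  ``holm``
    opts into a Holm-adjusted p column.
    """
    by_id = {r.participant_id: r for r in cohort}
    ids = [m.participant_id for m in metrics]
    if len(by_id) != len(cohort) or sorted(ids) != sorted(by_id):
        raise InputError("metrics and cohort records must match one-to-one on participant_id")
    fem = [m for m in metrics if by_id[m.participant_id].sex_label == "female"]
    mal = [m for m in metrics if by_id[m.participant_id].sex_label == "male"]
    if not fem or not mal:
        raise InputError("both sex groups must be nonempty")

    if include_performance is None:
        include_performance = all(r.performance_pct is not None for r in cohort)
    names = list(metric_names) + (["performance_pct"] if include_performance else [])

    comparisons: list[GroupComparison] = []
    for name in names:
        if name == "performance_pct":
            xa = np.array(
                [by_id[m.participant_id].performance_pct for m in fem], dtype=float
            )
            xb = np.array(
                [by_id[m.participant_id].performance_pct for m in mal], dtype=float
            )
            xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        else:
            xa = _group_values(fem, name)
            xb = _group_values(mal, name)
        if xa.size == 0 or xb.size == 0:
            raise InputError(f"metric {name!r} has no finite values in one group")
        u, p = mann_whitney_u(xa, xb, method=mw_method)
        comparisons.append(
            GroupComparison(
                metric_name=name,
                n_a=int(xa.size),
                n_b=int(xb.size),
                mean_a=float(xa.mean()),
                mean_b=float(xb.mean()),
                dispersion_a=float(xa.std(ddof=1) / math.sqrt(xa.size)) if xa.size > 1 else math.nan,
                dispersion_b=float(xb.std(ddof=1) / math.sqrt(xb.size)) if xb.size > 1 else math.nan,
                u_statistic=u,
                p_value=p,
            )
        )
    if holm:
        adj = multipletests([c.p_value for c in comparisons], method="holm")[1]
        comparisons = [
            GroupComparison(**{**c.__dict__, "p_holm": float(q)})
            for c, q in zip(comparisons, adj)
        ]

    def _counts(rows: list[ParticipantMetrics], pred) -> tuple[int, int]:
        gis = np.array([r.gaze_index for r in rows], dtype=float)
        gis = gis[np.isfinite(gis)]
        hit = int(pred(gis).sum())
        return hit, int(gis.size - hit)

    or_rows: list[OddsRatioRow] = []

    def _or_row(contrast: str, t: FourfoldTable) -> OddsRatioRow:
        # a toy cohort can leave an outcome bin empty; report the counts with
        # an undefined (NaN) odds ratio rather than failing the whole panel
        try:
            orr, (lo, hi) = odds_ratio(t)
        except ValueError:
            orr = lo = hi = math.nan
        return OddsRatioRow(contrast, t.a, t.b, t.c, t.d, orr, lo, hi)

    # superstarers (GI > 5): odds of being a superstarer, male vs female
    ma, mb = _counts(mal, lambda g: g > 5.0)
    fa, fb = _counts(fem, lambda g: g > 5.0)
    or_rows.append(_or_row("gi_gt5_male_vs_female", FourfoldTable(ma, mb, fa, fb)))
    # superscanners (GI < 1): odds of being a superscanner, female vs male
    fa, fb = _counts(fem, lambda g: g < 1.0)
    ma, mb = _counts(mal, lambda g: g < 1.0)
    or_rows.append(_or_row("gi_lt1_female_vs_male", FourfoldTable(fa, fb, ma, mb)))
    return comparisons, or_rows
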