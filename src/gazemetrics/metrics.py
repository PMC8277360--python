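"""Per-participant gaze metric suite, including the Gaze Index.

The Gaze Index (GI) is the ratio of time spent in long fixation ("staring")
to time spent in saccadic motion plus microfixations ("scanning"):

    GI = sum(fixation durations) / (sum(saccade durations) + sum(microfixation durations))

Microfixations count toward the scanning denominator because the reading
pattern is a saccade-microfixation-saccade chain; the numerator is
full-fixation time only.  Because both numerator and denominator are portions
of on-screen time, the GI is independent of how long a participant viewed the
screen: it normalizes for screen time by construction.

Screen time is fixation + microfixation + saccade time; off-screen episodes
(looks at paper notes, track loss) are excluded.  All "per minute" rates are
per minute of screen time.  The alternative normalization of saccade distance
per minute of *saccadic* time is exposed as an extra output column
(``saccade_px_per_saccade_min``).

GI categories: GI < 1 superscanner, 1 <= GI < 3 scanner, 3 <= GI <= 5 starer,
GI > 5 superstarer.  GI exactly 3 bins as starer (a measure-zero tie; the
defining inequalities are strict and never address equality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedGazeIndexError
from .events import FIXATION, MICROFIXATION, OFFSCREEN, SACCADE, EventSequence
from .io import GazeStream

__all__ = [
    "ParticipantMetrics",
    "gaze_index",
    "gi_category",
    "compute_metrics",
    "metrics_frame",
    "metrics_from_frame",
]

GI_CATEGORIES = ("superscanner", "scanner", "starer", "superstarer")


@dataclass(frozen=True)
class ParticipantMetrics:
    """The per-participant metric suite.

    Undefined quantities (no screen time, fewer than two full fixations,
    zero scanning time) are NaN / ``None`` rather than raising, so cohort
    tables stay rectangular.
    """

    participant_id: str
    screen_time_fraction: float
    fixations_per_min: float
    mean_fixation_ms: float
    mean_interfixation_px: float
    saccade_px_per_min: float
    saccades_per_min: float
    mean_saccade_ms: float
    gaze_index: float
    gi_category: str | None
    saccade_px_per_saccade_min: float = math.nan


def gaze_index(events: EventSequence) -> float:
    """Gaze Index: full-fixation ("stare") time over scanning (saccade + microfixation) time.

    Raises :class:`UndefinedGazeIndexError` when scanning time is zero (the
    ratio is undefined, not infinite).
    """
    dur = events.durations_ms
    stare = dur[events.kinds == FIXATION].sum()
    scan = dur[(events.kinds == SACCADE) | (events.kinds == MICROFIXATION)].sum()
    if scan <= 0:
        raise UndefinedGazeIndexError("zero scanning time: Gaze Index is undefined")
    return float(stare / scan)


def gi_category(gi: float) -> str:
    """Bin a Gaze Index value into superscanner / scanner / starer / superstarer."""
    if not (isinstance(gi, (int, float)) and math.isfinite(gi) and gi > 0):
        raise ValueError(f"Gaze Index must be a positive finite number, got {gi!r}")
    if gi < 1.0:
        return "superscanner"
    if gi < 3.0:
        return "scanner"
    if gi <= 5.0:
        return "starer"
    return "superstarer"


def _interfixation_px(events: EventSequence) -> float:
    """Mean Euclidean distance between successive full-fixation centroids.

    Intervening microfixations and saccades are skipped; a pair separated by
    an off-screen episode is not counted (gaze relocates while unobserved, so
    the jump is not screen distance traveled).
    """
    k = events.kinds
    dists = []
    prev = None  # index of previous fixation, None after an offscreen break
    for i in range(k.size):
        if k[i] == OFFSCREEN:
            prev = None
        elif k[i] == FIXATION:
            if prev is not None:
                dists.append(
                    math.hypot(
                        events.centroid_x_px[i] - events.centroid_x_px[prev],
                        events.centroid_y_px[i] - events.centroid_y_px[prev],
                    )
                )
            prev = i
    return float(np.mean(dists)) if dists else math.nan


def compute_metrics(
    events: EventSequence,
    stream: GazeStream | None = None,
    *,
    task_duration_ms: float | None = None,
) -> ParticipantMetrics:
    """Compute the full metric suite for one participant.

    ``task_duration_ms`` is taken from ``stream`` when given.  Depends only on
    the ordered event list; re-running is bit-identical.
    """
    if task_duration_ms is None:
        if stream is None:
            raise ValueError("either stream or task_duration_ms is required")
        task_duration_ms = stream.task_duration_ms
    dur = events.durations_ms
    k = events.kinds
    fix_t = float(dur[k == FIXATION].sum())
    micro_t = float(dur[k == MICROFIXATION].sum())
    sac_mask = k == SACCADE
    sac_t = float(dur[sac_mask].sum())
    n_fix = int((k == FIXATION).sum())
    n_sac = int(sac_mask.sum())
    screen_ms = fix_t + micro_t + sac_t
    screen_min = screen_ms / 60_000.0
    path_px = float(np.nansum(events.path_length_px[sac_mask])) if n_sac else 0.0

    if screen_min > 0:
        fixations_per_min = n_fix / screen_min
        saccades_per_min = n_sac / screen_min
        saccade_px_per_min = path_px / screen_min
    else:
        fixations_per_min = saccades_per_min = saccade_px_per_min = math.nan
    mean_fixation_ms = fix_t / n_fix if n_fix else math.nan
    mean_saccade_ms = sac_t / n_sac if n_sac else math.nan
    sac_min = sac_t / 60_000.0
    saccade_px_per_saccade_min = path_px / sac_min if sac_min > 0 else math.nan
    try:
        gi = gaze_index(events)
        cat = gi_category(gi) if gi > 0 else None
    except UndefinedGazeIndexError:
        gi, cat = math.nan, None
    return ParticipantMetrics(
        participant_id=events.participant_id,
        screen_time_fraction=screen_ms / task_duration_ms,
        fixations_per_min=fixations_per_min,
        mean_fixation_ms=mean_fixation_ms,
        mean_interfixation_px=_interfixation_px(events),
        saccade_px_per_min=saccade_px_per_min,
        saccades_per_min=saccades_per_min,
        mean_saccade_ms=mean_saccade_ms,
        gaze_index=gi,
        gi_category=cat,
        saccade_px_per_saccade_min=saccade_px_per_saccade_min,
    )


def metrics_frame(rows: list[ParticipantMetrics]) -> pd.DataFrame:
    """Stack ParticipantMetrics records into a tidy DataFrame."""
    from dataclasses import asdict

    return pd.DataFrame([asdict(r) for r in rows])


def metrics_from_frame(df: pd.DataFrame) -> list[ParticipantMetrics]:
    """Rebuild ParticipantMetrics records from a metrics table (CSV round-trip)."""
    out = []
    for _, r in df.iterrows():
        cat = r.get("gi_category")
        out.append(
            ParticipantMetrics(
                participant_id=str(r["participant_id"]),
                screen_time_fraction=float(r["screen_time_fraction"]),
                fixations_per_min=float(r["fixations_per_min"]),
                mean_fixation_ms=float(r["mean_fixation_ms"]),
                mean_interfixation_px=float(r["mean_interfixation_px"]),
                saccade_px_per_min=float(r["saccade_px_per_min"]),
                saccades_per_min=float(r["saccades_per_min"]),
                mean_saccade_ms=float(r["mean_saccade_ms"]),
                gaze_index=float(r["gaze_index"]),
                gi_category=None if pd.isna(cat) else str(cat),
                saccade_px_per_saccade_min=float(r.get("saccade_px_per_saccade_min", math.nan)),
            )
        )
    return out
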