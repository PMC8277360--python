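"""Velocity-threshold (I-VT) gaze event classification with a microfixation tier.

A gaze stream is segmented into four mutually exclusive, contiguous event
kinds.  Each inter-sample interval is labeled independently and maximal runs
of equal labels are merged:

* intervals touching an invalid sample -> **offscreen**;
* intervals with angular velocity strictly above the threshold (default
  30 deg/s) -> **saccade**;
* remaining sub-threshold runs -> **fixation** if the run lasts strictly
  longer than the minimum fixation duration (default 60 ms), otherwise
  **microfixation** (the short stationary dwell characteristic of reading
  chains).

The velocity estimator is the plain two-point sample-to-sample estimate, with
no smoothing window: at ~30 Hz multi-point estimators are under-determined,
and the classification rule is defined purely by a threshold.  The estimator
is isolated in :func:`angular_velocity` as a seam for future alternatives.
No vendor-style noise filtering is applied before thresholding.

Boundary conventions: an interval exactly at the threshold is non-saccadic
(the rule is "exceeding"); a sub-threshold run of exactly the minimum duration
is a microfixation (the fixation rule is "longer than").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ClassificationError, FormatError
from .io import GazeSample, GazeStream, ScreenGeometry

__all__ = [
    "ClassifierParams",
    "GazeEvent",
    "EventSequence",
    "FIXATION",
    "MICROFIXATION",
    "SACCADE",
    "OFFSCREEN",
    "KIND_NAMES",
    "pixels_to_degrees",
    "degrees_to_pixels",
    "linear_deg_per_px",
    "angular_velocity",
    "classify_events",
]

# integer event codes used in the columnar EventSequence representation
FIXATION, MICROFIXATION, SACCADE, OFFSCREEN = 0, 1, 2, 3
KIND_NAMES = ("fixation", "microfixation", "saccade", "offscreen")
_KIND_CODE = {name: code for code, name in enumerate(KIND_NAMES)}


@dataclass(frozen=True)
class ClassifierParams:
    """I-VT thresholds: velocity cut (deg/s) and minimum full-fixation duration (ms)."""

    velocity_threshold_deg_s: float = 30.0
    min_fixation_ms: float = 60.0

    def __post_init__(self) -> None:
        if self.velocity_threshold_deg_s <= 0 or self.min_fixation_ms <= 0:
            raise ValueError("classifier thresholds must be strictly positive")


def pixels_to_degrees(displacement_px: float, geometry: ScreenGeometry):
    """Convert an on-screen pixel displacement to degrees of visual angle.

    theta = 2 * atan(d_cm / (2 * D_cm)) with d_cm the physical displacement
    (horizontal pixel pitch) and D the viewing distance.  Monotone in the
    displacement; accepts scalars or arrays.
    """
    d = np.asarray(displacement_px, dtype=float)
    if (d < 0).any():
        raise ValueError("displacement must be nonnegative")
    theta = 2.0 * np.arctan(d * geometry.pitch_cm / (2.0 * geometry.viewing_distance_cm))
    out = np.degrees(theta)
    return float(out) if np.isscalar(displacement_px) else out


def degrees_to_pixels(angle_deg: float, geometry: ScreenGeometry) -> float:
    """Inverse of :func:`pixels_to_degrees` (exact, tangent-based)."""
    if angle_deg < 0:
        raise ValueError("angle must be nonnegative")
    return (
        2.0
        * geometry.viewing_distance_cm
        * math.tan(math.radians(angle_deg) / 2.0)
        / geometry.pitch_cm
    )


def linear_deg_per_px(geometry: ScreenGeometry) -> float:
    """Small-angle (linear) degrees per pixel; the derivative of the conversion at 0."""
    return math.degrees(geometry.pitch_cm / geometry.viewing_distance_cm)


def angular_velocity(prev: GazeSample, nxt: GazeSample, geometry: ScreenGeometry) -> float:
    """Two-point angular velocity (deg/s) over the interval between two valid samples.

    The estimate belongs to the interval and is reported at the later sample.
    """
    if not (prev.valid and nxt.valid):
        raise ValueError("angular velocity requires two valid samples")
    dt_s = (nxt.t_ms - prev.t_ms) / 1000.0
    if dt_s <= 0:
        raise ValueError("samples must be in strictly increasing time order")
    disp = math.hypot(nxt.x_px - prev.x_px, nxt.y_px - prev.y_px)
    return pixels_to_degrees(disp, geometry) / dt_s


@dataclass(frozen=True)
class GazeEvent:
    """One classified gaze event.

    ``centroid_*`` is set for fixations/microfixations (unweighted mean of
    member-sample coordinates); ``path_length_px`` is the within-event
    polyline length, set for saccades.
    """

    kind: str
    start_ms: float
    end_ms: float
    centroid_x_px: float | None = None
    centroid_y_px: float | None = None
    path_length_px: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KIND_NAMES:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.end_ms > self.start_ms:
            raise ValueError("event duration must be strictly positive")

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


class EventSequence:
    """Ordered, contiguous, non-overlapping event list covering one recording.

    Stored columnar (parallel numpy arrays, one entry per event).  Invariants:
    strictly positive durations; events contiguous (each starts where the
    previous ends); no two consecutive events of identical kind (equal-label
    runs are merged by construction, including saccade-saccade).

    Hand-built sequences (e.g. for worked examples) are validated against the
    same structural invariants, but kind/duration coupling (a fixation being
    longer than the classifier minimum) is a property of classifier output,
    not of the container.
    """

    def __init__(
        self,
        participant_id: str,
        kinds: Sequence[int],
        start_ms: Sequence[float],
        end_ms: Sequence[float],
        centroid_x_px: Sequence[float] | None = None,
        centroid_y_px: Sequence[float] | None = None,
        path_length_px: Sequence[float] | None = None,
    ) -> None:
        k = np.asarray(kinds, dtype=np.int8)
        s = np.asarray(start_ms, dtype=float)
        e = np.asarray(end_ms, dtype=float)
        n = k.size
        if not (s.size == e.size == n):
            raise ValueError("kinds, start_ms, end_ms must have equal length")
        if n == 0:
            raise ValueError("an event sequence must contain at least one event")
        if not ((k >= 0) & (k <= 3)).all():
            raise ValueError("unknown event kind code")
        if not (e > s).all():
            raise ValueError("event durations must be strictly positive")
        if n > 1 and not np.allclose(s[1:], e[:-1], rtol=0.0, atol=1e-9):
            raise FormatError("events must be contiguous")
        if n > 1 and (k[1:] == k[:-1]).any():
            raise FormatError("consecutive events of identical kind must be merged")
        self.participant_id = str(participant_id)
        self.kinds = k
        self.start_ms = s
        self.end_ms = e
        nan = np.full(n, np.nan)
        self.centroid_x_px = nan.copy() if centroid_x_px is None else np.asarray(centroid_x_px, float)
        self.centroid_y_px = nan.copy() if centroid_y_px is None else np.asarray(centroid_y_px, float)
        self.path_length_px = nan.copy() if path_length_px is None else np.asarray(path_length_px, float)

    @classmethod
    def from_events(cls, participant_id: str, events: Iterable[GazeEvent]) -> "EventSequence":
        evs = list(events)
        return cls(
            participant_id,
            [_KIND_CODE[e.kind] for e in evs],
            [e.start_ms for e in evs],
            [e.end_ms for e in evs],
            [np.nan if e.centroid_x_px is None else e.centroid_x_px for e in evs],
            [np.nan if e.centroid_y_px is None else e.centroid_y_px for e in evs],
            [np.nan if e.path_length_px is None else e.path_length_px for e in evs],
        )

    @property
    def durations_ms(self) -> np.ndarray:
        return self.end_ms - self.start_ms

    @property
    def events(self) -> list[GazeEvent]:
        out = []
        for i in range(len(self)):
            cx, cy, pl = self.centroid_x_px[i], self.centroid_y_px[i], self.path_length_px[i]
            out.append(
                GazeEvent(
                    KIND_NAMES[self.kinds[i]],
                    float(self.start_ms[i]),
                    float(self.end_ms[i]),
                    None if np.isnan(cx) else float(cx),
                    None if np.isnan(cy) else float(cy),
                    None if np.isnan(pl) else float(pl),
                )
            )
        return out

    def __len__(self) -> int:
        return int(self.kinds.size)

    def to_frame(self) -> pd.DataFrame:
        """Tidy event table (one row per event; empty cells where inapplicable)."""
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "kind": [KIND_NAMES[c] for c in self.kinds],
                "start_ms": self.start_ms,
                "end_ms": self.end_ms,
                "duration_ms": self.durations_ms,
                "centroid_x_px": self.centroid_x_px,
                "centroid_y_px": self.centroid_y_px,
                "path_length_px": self.path_length_px,
            }
        )


def _interval_codes(stream: GazeStream, params: ClassifierParams) -> np.ndarray:
    """Label every inter-sample interval: FIXATION (sub-threshold candidate),
    SACCADE, or OFFSCREEN."""
    t, x, y, v = stream.t_ms, stream.x_px, stream.y_px, stream.valid
    both_valid = v[:-1] & v[1:]
    codes = np.full(t.size - 1, OFFSCREEN, dtype=np.int8)
    if both_valid.any():
        dx = x[1:] - x[:-1]
        dy = y[1:] - y[:-1]
        disp = np.hypot(np.where(both_valid, dx, 0.0), np.where(both_valid, dy, 0.0))
        dt_s = (t[1:] - t[:-1]) / 1000.0
        vel = pixels_to_degrees(disp, stream.geometry) / dt_s
        sac = both_valid & (vel > params.velocity_threshold_deg_s)
        sub = both_valid & ~sac
        codes[sac] = SACCADE
        codes[sub] = FIXATION
    return codes


def classify_events(
    stream: GazeStream, params: ClassifierParams = ClassifierParams()
) -> EventSequence:
    """Segment a gaze stream into fixation/microfixation/saccade/offscreen events.

    Deterministic: identical input yields a bit-identical event list.  The
    resulting sequence is contiguous over ``[first sample, last sample]`` and
    event durations sum exactly to that span.
    """
    if len(stream) < 2:
        raise ClassificationError("classification requires at least 2 samples")
    t, x, y = stream.t_ms, stream.x_px, stream.y_px
    codes = _interval_codes(stream, params)

    # maximal runs of equal interval labels
    change = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    starts = np.concatenate(([0], change))          # first interval index of each run
    ends = np.concatenate((change, [codes.size]))   # one past last interval index

    n = starts.size
    kinds = np.empty(n, dtype=np.int8)
    ev_start = t[starts]
    ev_end = t[ends]
    cx = np.full(n, np.nan)
    cy = np.full(n, np.nan)
    pl = np.full(n, np.nan)
    for i in range(n):
        a, b = starts[i], ends[i]
        code = codes[a]
        if code == FIXATION:
            dur = t[b] - t[a]
            kinds[i] = FIXATION if dur > params.min_fixation_ms else MICROFIXATION
            cx[i] = x[a : b + 1].mean()
            cy[i] = y[a : b + 1].mean()
        elif code == SACCADE:
            kinds[i] = SACCADE
            pl[i] = np.hypot(np.diff(x[a : b + 1]), np.diff(y[a : b + 1])).sum()
        else:
            kinds[i] = OFFSCREEN
    return EventSequence(stream.participant_id, kinds, ev_start, ev_end, cx, cy, pl)
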