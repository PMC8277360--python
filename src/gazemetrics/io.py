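"""Gaze-stream files, screen geometry, cohort metadata, and result tables.

Conventions
-----------
Coordinates use the tracker-export convention: origin at the top-left corner of
the screen, x increasing rightward, y increasing downward, 0-based pixels.
Timestamps are milliseconds from task start (integer or fractional).

Stream files are delimited text (comma or tab, auto-detected) with a header row
``t_ms,x_px,y_px[,valid]``.  Invalid samples (track loss, gaze off the monitor)
are retained with ``valid`` false rather than dropped: off-screen time is itself
an analyzed quantity.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass
from typing import ClassVar, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InputError

__all__ = [
    "ScreenGeometry",
    "GazeSample",
    "GazeStream",
    "CohortRecord",
    "EXAMPLE_GEOMETRY",
    "read_gaze_stream",
    "write_stream",
    "write_results_table",
    "read_cohort",
    "write_cohort",
    "load_config",
    "geometry_from_dict",
]

#: Sanity band for the physical pixel pitch (cm per pixel) of any plausible
#: desktop monitor; values outside it almost always indicate swapped units.
PIXEL_PITCH_BAND = (0.01, 0.1)


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and pixel dimensions of the monitor plus viewing distance.

    The default viewing distance is 65 cm (fixed chair/monitor placement).
    """

    width_px: float
    height_px: float
    width_cm: float
    height_cm: float
    viewing_distance_cm: float = 65.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"ScreenGeometry.{f.name} must be strictly positive, got {v!r}")
        lo, hi = PIXEL_PITCH_BAND
        if not (lo <= self.pitch_cm <= hi):
            raise ValueError(
                f"pixel pitch {self.pitch_cm:.4g} cm/px outside sanity band {PIXEL_PITCH_BAND}"
            )

    @property
    def pitch_cm(self) -> float:
        """Horizontal pixel pitch in cm per pixel."""
        return self.width_cm / self.width_px


#: Documented example geometry (1280x1024 px on a 33.7x27.0 cm panel at 65 cm).
#: The monitor model of any particular recording setup must be supplied by the
#: user; this is a realistic default for a monitor-mounted tracker workstation.
EXAMPLE_GEOMETRY = ScreenGeometry(1280, 1024, 33.7, 27.0, 65.0)


@dataclass(frozen=True)
class GazeSample:
    """One raw tracker sample. ``valid`` means a gaze point on screen was reported."""

    t_ms: float
    x_px: float
    y_px: float
    valid: bool = True


class GazeStream:
    """Timestamped gaze-sample sequence for one participant.

    Stored columnar (numpy arrays) for speed; :attr:`samples` materializes
    :class:`GazeSample` objects.  Invariants enforced at construction:
    timestamps strictly increasing and nonnegative; valid samples lie inside
    screen bounds; ``task_duration_ms`` covers the last timestamp.
    """

    def __init__(
        self,
        participant_id: str,
        geometry: ScreenGeometry,
        t_ms: Sequence[float],
        x_px: Sequence[float],
        y_px: Sequence[float],
        valid: Sequence[bool] | None = None,
        *,
        nominal_rate_hz: float = 30.0,
        task_duration_ms: float = 600_000.0,
    ) -> None:
        t = np.asarray(t_ms, dtype=float)
        x = np.asarray(x_px, dtype=float)
        y = np.asarray(y_px, dtype=float)
        if valid is None:
            v = np.ones(t.shape, dtype=bool)
        else:
            v = np.asarray(valid, dtype=bool)
        if not (t.shape == x.shape == y.shape == v.shape) or t.ndim != 1:
            raise ValueError("t_ms, x_px, y_px, valid must be 1-D arrays of equal length")
        if t.size and (not np.isfinite(t).all() or t[0] < 0):
            raise ValueError("timestamps must be finite and nonnegative")
        if t.size > 1 and not (np.diff(t) > 0).all():
            raise FormatError("timestamps must be strictly increasing")
        if t.size and task_duration_ms < t[-1]:
            raise ValueError(
                f"task_duration_ms={task_duration_ms} is before the last sample at {t[-1]} ms"
            )
        vx, vy = x[v], y[v]
        if vx.size and (
            not np.isfinite(vx).all()
            or not np.isfinite(vy).all()
            or (vx < 0).any()
            or (vx >= geometry.width_px).any()
            or (vy < 0).any()
            or (vy >= geometry.height_px).any()
        ):
            raise ValueError("valid samples must have finite coordinates inside screen bounds")
        if nominal_rate_hz <= 0:
            raise ValueError("nominal_rate_hz must be positive")
        self.participant_id = str(participant_id)
        self.geometry = geometry
        self.t_ms = t
        self.x_px = x
        self.y_px = y
        self.valid = v
        self.nominal_rate_hz = float(nominal_rate_hz)
        self.task_duration_ms = float(task_duration_ms)

    @classmethod
    def from_samples(
        cls,
        participant_id: str,
        samples: Iterable[GazeSample],
        geometry: ScreenGeometry,
        *,
        nominal_rate_hz: float = 30.0,
        task_duration_ms: float = 600_000.0,
    ) -> "GazeStream":
        ss = list(samples)
        return cls(
            participant_id,
            geometry,
            [s.t_ms for s in ss],
            [s.x_px for s in ss],
            [s.y_px for s in ss],
            [s.valid for s in ss],
            nominal_rate_hz=nominal_rate_hz,
            task_duration_ms=task_duration_ms,
        )

    @property
    def samples(self) -> list[GazeSample]:
        return [
            GazeSample(float(t), float(x), float(y), bool(v))
            for t, x, y, v in zip(self.t_ms, self.x_px, self.y_px, self.valid)
        ]

    def __len__(self) -> int:
        return int(self.t_ms.size)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"GazeStream({self.participant_id!r}, n={len(self)}, "
            f"rate={self.nominal_rate_hz} Hz, task={self.task_duration_ms} ms)"
        )


@dataclass(frozen=True)
class CohortRecord:
    """Per-participant cohort metadata (sex label, optional specialty/performance)."""

    participant_id: str
    sex_label: str
    specialty: str | None = None
    performance_pct: float | None = None

    def __post_init__(self) -> None:
        if self.sex_label not in ("female", "male"):
            raise ValueError(f"sex_label must be 'female' or 'male', got {self.sex_label!r}")
        if self.performance_pct is not None and not (0.0 <= self.performance_pct <= 100.0):
            raise ValueError("performance_pct must lie in [0, 100]")


# ---------------------------------------------------------------------------
# stream files
# ---------------------------------------------------------------------------

_STREAM_COLUMNS = ("t_ms", "x_px", "y_px")


def read_gaze_stream(
    path: str | os.PathLike,
    geometry: ScreenGeometry,
    nominal_rate_hz: float = 30.0,
    *,
    participant_id: str | None = None,
    task_duration_ms: float | None = None,
) -> GazeStream:
    """Read a delimited gaze-sample file into a :class:`GazeStream`.

    The delimiter (comma or tab) is auto-detected.  Rows are sorted by
    timestamp and exact duplicate timestamps are rejected (first occurrence
    kept).  A missing ``valid`` column is inferred from coordinates lying
    inside screen bounds; samples flagged valid but out of bounds or
    non-finite are demoted to invalid.
    """
    with open(path) as fh:
        if not fh.read(4096).strip():
            raise InputError(f"empty gaze-stream file: {path}")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty gaze-stream file: {path}") from exc
    if df.empty and df.columns.size == 0:
        raise InputError(f"empty gaze-stream file: {path}")
    missing = [c for c in _STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df = df.sort_values("t_ms", kind="stable")
    df = df[~df["t_ms"].duplicated(keep="first")]
    t = df["t_ms"].to_numpy(float)
    if t.size == 0:
        raise InputError(f"no samples in gaze-stream file: {path}")
    if not np.isfinite(t).all():
        raise FormatError(f"{path}: non-numeric timestamps")
    x = df["x_px"].to_numpy(float)
    y = df["y_px"].to_numpy(float)
    # corrupt-export guard: a physically implausible coordinate band
    finite = np.isfinite(x) & np.isfinite(y)
    if (
        (x[finite] < -geometry.width_px).any()
        or (x[finite] > 2 * geometry.width_px).any()
        or (y[finite] < -geometry.height_px).any()
        or (y[finite] > 2 * geometry.height_px).any()
    ):
        raise FormatError(f"{path}: coordinates far outside the screen; corrupt export?")
    in_bounds = (
        finite
        & (x >= 0)
        & (x < geometry.width_px)
        & (y >= 0)
        & (y < geometry.height_px)
    )
    if "valid" in df.columns:
        v = df["valid"].astype(bool).to_numpy() & in_bounds
    else:
        v = in_bounds
    if participant_id is None:
        participant_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    if task_duration_ms is None:
        task_duration_ms = max(600_000.0, float(t[-1]))
    return GazeStream(
        participant_id,
        geometry,
        t,
        x,
        y,
        v,
        nominal_rate_hz=nominal_rate_hz,
        task_duration_ms=task_duration_ms,
    )


def write_stream(stream: GazeStream, path: str | os.PathLike) -> str:
    """Write a stream as CSV, re-readable by :func:`read_gaze_stream` value-identically."""
    df = pd.DataFrame(
        {
            "t_ms": stream.t_ms,
            "x_px": stream.x_px,
            "y_px": stream.y_px,
            "valid": stream.valid.astype(int),
        }
    )
    df.to_csv(path, index=False)
    return os.fspath(path)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def _row_frame(rows: Sequence) -> pd.DataFrame:
    kinds = {type(r) for r in rows}
    if len(kinds) > 1:
        raise ValueError(f"mixed row kinds in results table: {sorted(k.__name__ for k in kinds)}")
    cls = next(iter(kinds))
    if not dataclasses.is_dataclass(cls):
        raise TypeError(f"rows must be dataclass records, got {cls.__name__}")
    cols = [f.name for f in dataclasses.fields(cls)]
    rename: dict = getattr(cls, "_csv_rename", {})
    df = pd.DataFrame([[getattr(r, c) for c in cols] for r in rows], columns=cols)
    # opt-in columns are omitted when no row carries a value
    for c in getattr(cls, "_csv_optional", ()):
        if c in df.columns and df[c].isna().all():
            df = df.drop(columns=[c])
    return df.rename(columns=rename)


def write_results_table(rows: Sequence, path: str | os.PathLike, *, kind=None) -> str:
    """Write a homogeneous sequence of result records as a tidy CSV.

    Column order follows the record type's field order (documented in the
    header row).  With zero rows, ``kind`` (the record dataclass) must be
    given so the header can still be written.
    """
    if len(rows) == 0:
        if kind is None:
            raise ValueError("kind= is required to write a header-only table")
        optional = getattr(kind, "_csv_optional", ())
        cols = [f.name for f in dataclasses.fields(kind) if f.name not in optional]
        rename = getattr(kind, "_csv_rename", {})
        df = pd.DataFrame(columns=[rename.get(c, c) for c in cols])
    else:
        df = _row_frame(rows)
    df.to_csv(path, index=False)
    return os.fspath(path)


def write_cohort(records: Sequence[CohortRecord], path: str | os.PathLike) -> str:
    return write_results_table(records, path, kind=CohortRecord)


def read_cohort(path: str | os.PathLike) -> list[CohortRecord]:
    df = pd.read_csv(path)
    if "sex_label" not in df.columns:
        raise FormatError(f"{path}: cohort file is missing the sex_label column")
    out = []
    for _, r in df.iterrows():
        perf = r.get("performance_pct")
        spec = r.get("specialty")
        out.append(
            CohortRecord(
                participant_id=str(r["participant_id"]),
                sex_label=str(r["sex_label"]),
                specialty=None if pd.isna(spec) else str(spec),
                performance_pct=None if perf is None or pd.isna(perf) else float(perf),
            )
        )
    return out


# ---------------------------------------------------------------------------
# flat key-value config
# ---------------------------------------------------------------------------

_GEOMETRY_KEYS = ("width_px", "height_px", "width_cm", "height_cm", "viewing_distance_cm")


def load_config(path: str | os.PathLike) -> dict:
    """Load a flat key-value config file (YAML mapping of scalars)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a flat key-value mapping")
    return cfg


def geometry_from_dict(cfg: dict) -> ScreenGeometry:
    missing = [k for k in _GEOMETRY_KEYS if k not in cfg]
    if missing:
        raise FormatError(f"config missing geometry keys {missing}")
    return ScreenGeometry(**{k: float(cfg[k]) for k in _GEOMETRY_KEYS})
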