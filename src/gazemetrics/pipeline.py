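"""End-to-end orchestration: streams -> events -> metrics -> cohort comparisons.

``run_analysis`` either simulates a cohort or reads stream files from a
directory, classifies every stream, computes the per-participant metric
suite, and (when cohort sex labels are available and comparison is enabled)
produces the group-comparison panel, the odds-ratio rows at the GI extremes,
and a Gaze Index distribution summary.  A machine-readable run manifest
(JSON lines) records thresholds, seed, and package version so results are
reproducible; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import os
from dataclasses import dataclass, field

from . import __version__
from .errors import InputError
from .events import ClassifierParams, classify_events
from .io import (
    EXAMPLE_GEOMETRY,
    CohortRecord,
    GazeStream,
    ScreenGeometry,
    read_cohort,
    read_gaze_stream,
    write_cohort,
    write_results_table,
    write_stream,
)
from .metrics import ParticipantMetrics, compute_metrics
from .simulate import CohortSpec, generate_cohort
from .stats import GroupComparison, OddsRatioRow, compare_cohort

__all__ = ["RunConfig", "RunResult", "run_analysis", "gi_summary"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``input_dir`` / ``simulate`` must be set.  In simulate
    mode ``cohort_spec`` describes the synthetic cohort (defaults used when
    omitted); ``seed`` overrides the spec's seed.
    """

    output_dir: str
    input_dir: str | None = None
    simulate: bool = False
    cohort_spec: CohortSpec | None = None
    geometry: ScreenGeometry = field(default_factory=lambda: EXAMPLE_GEOMETRY)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    nominal_rate_hz: float = 30.0
    seed: int | None = None
    compare: bool = True
    holm: bool = False
    write_streams: bool = False

    def __post_init__(self) -> None:
        if bool(self.input_dir) == bool(self.simulate):
            raise ValueError("exactly one of input_dir / simulate must be set")


@dataclass
class RunResult:
    metrics: list[ParticipantMetrics]
    comparisons: list[GroupComparison]
    or_rows: list[OddsRatioRow]
    gi_summary: dict


def gi_summary(metrics: list[ParticipantMetrics]) -> dict:
    """GI distribution summary: range, mean, and counts in the named bins."""
    import numpy as np

    gis = np.array([m.gaze_index for m in metrics], dtype=float)
    gis = gis[np.isfinite(gis)]
    if gis.size == 0:
        return {"n": 0}
    return {
        "n": int(gis.size),
        "min": float(gis.min()),
        "max": float(gis.max()),
        "mean": float(gis.mean()),
        "n_gt3": int((gis > 3.0).sum()),
        "n_lt3": int((gis < 3.0).sum()),
        "n_lt1": int((gis < 1.0).sum()),
        "n_gt5": int((gis > 5.0).sum()),
    }


def _load_streams(cfg: RunConfig) -> tuple[list[GazeStream], list[CohortRecord] | None]:
    paths = sorted(
        p
        for p in glob.glob(os.path.join(cfg.input_dir, "*"))
        if p.endswith((".csv", ".tsv")) and not p.endswith("cohort.csv")
    )
    if not paths:
        raise InputError(f"no stream files (*.csv, *.tsv) found in {cfg.input_dir}")
    streams = [
        read_gaze_stream(p, cfg.geometry, cfg.nominal_rate_hz) for p in paths
    ]
    cohort_path = os.path.join(cfg.input_dir, "cohort.csv")
    cohort = read_cohort(cohort_path) if os.path.exists(cohort_path) else None
    return streams, cohort


def run_analysis(cfg: RunConfig) -> RunResult:
    """Run the full pipeline and write result tables under ``cfg.output_dir``."""
    os.makedirs(cfg.output_dir, exist_ok=True)
    if cfg.simulate:
        spec = cfg.cohort_spec or CohortSpec()
        if cfg.seed is not None:
            spec = dataclasses.replace(spec, seed=cfg.seed)
        streams, cohort = generate_cohort(spec)
        if cfg.write_streams:
            for s in streams:
                write_stream(s, os.path.join(cfg.output_dir, f"{s.participant_id}.csv"))
        write_cohort(cohort, os.path.join(cfg.output_dir, "cohort.csv"))
    else:
        streams, cohort = _load_streams(cfg)

    metrics = [
        compute_metrics(classify_events(s, cfg.classifier), s) for s in streams
    ]
    write_results_table(
        metrics, os.path.join(cfg.output_dir, "metrics.csv"), kind=ParticipantMetrics
    )
    summary = gi_summary(metrics)
    with open(os.path.join(cfg.output_dir, "gi_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    comparisons: list[GroupComparison] = []
    or_rows: list[OddsRatioRow] = []
    if cfg.compare:
        if cohort is None:
            raise InputError("comparison requested but no cohort.csv with sex labels found")
        comparisons, or_rows = compare_cohort(metrics, cohort, holm=cfg.holm)
        write_results_table(
            comparisons,
            os.path.join(cfg.output_dir, "comparison.csv"),
            kind=GroupComparison,
        )
        write_results_table(
            or_rows, os.path.join(cfg.output_dir, "odds_ratios.csv"), kind=OddsRatioRow
        )

    manifest = {
        "tool": "gazemetrics",
        "version": __version__,
        "velocity_threshold_deg_s": cfg.classifier.velocity_threshold_deg_s,
        "min_fixation_ms": cfg.classifier.min_fixation_ms,
        "viewing_distance_cm": cfg.geometry.viewing_distance_cm,
        "nominal_rate_hz": cfg.nominal_rate_hz,
        "seed": cfg.seed,
        "mode": "simulate" if cfg.simulate else "input_dir",
        "n_streams": len(streams),
    }
    with open(os.path.join(cfg.output_dir, "run_manifest.jsonl"), "w") as fh:
        fh.write(json.dumps(manifest, sort_keys=True) + "\n")
    return RunResult(metrics, comparisons, or_rows, summary)
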