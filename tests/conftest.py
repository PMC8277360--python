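import numpy as np
import pandas as pd
import pytest

from gazemetrics import (
    EXAMPLE_GEOMETRY,
    CohortSpec,
    GazeStream,
    classify_events,
    compute_metrics,
    generate_cohort,
)


@pytest.fixture
def geometry():
    return EXAMPLE_GEOMETRY


def make_stream(points, geometry=EXAMPLE_GEOMETRY, *, rate_hz=30.0, task_ms=None,
                participant_id="p"):
    """Build a GazeStream from (t_ms, x_px, y_px[, valid]) tuples."""
    t = [p[0] for p in points]
    x = [p[1] for p in points]
    y = [p[2] for p in points]
    v = [p[3] if len(p) > 3 else True for p in points]
    if task_ms is None:
        task_ms = max(600_000.0, t[-1])
    return GazeStream(participant_id, geometry, t, x, y, v,
                      nominal_rate_hz=rate_hz, task_duration_ms=task_ms)


def random_stream(rng, n=None, geometry=EXAMPLE_GEOMETRY, p_invalid=0.15):
    """Random gaze stream mixing sub- and supra-threshold steps and track loss."""
    if n is None:
        n = int(rng.integers(2, 201))
    dt = rng.uniform(20.0, 45.0, n - 1)
    t = np.concatenate(([0.0], np.cumsum(dt)))
    x = np.empty(n)
    y = np.empty(n)
    x[0] = rng.uniform(50, geometry.width_px - 50)
    y[0] = rng.uniform(50, geometry.height_px - 50)
    for i in range(1, n):
        if rng.random() < 0.4:  # large jump (usually supra-threshold)
            step = rng.uniform(40.0, 200.0)
        else:  # jitter (usually sub-threshold)
            step = rng.uniform(0.0, 5.0)
        ang = rng.uniform(0, 2 * np.pi)
        x[i] = np.clip(x[i - 1] + step * np.cos(ang), 0, geometry.width_px - 1)
        y[i] = np.clip(y[i - 1] + step * np.sin(ang), 0, geometry.height_px - 1)
    valid = rng.random(n) >= p_invalid
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return GazeStream("rand", geometry, t, x, y, valid,
                      task_duration_ms=float(t[-1]) + 1.0)


@pytest.fixture(scope="session")
def default_cohort_frame():
    """Per-participant metrics for the default 46+47 cohort over 5 fixed seeds."""
    rows = []
    for seed in (101, 102, 103, 104, 105):
        streams, cohort = generate_cohort(CohortSpec(seed=seed))
        sex = {r.participant_id: r.sex_label for r in cohort}
        for s in streams:
            m = compute_metrics(classify_events(s), s)
            rows.append({"seed": seed, "sex": sex[m.participant_id], **m.__dict__})
    return pd.DataFrame(rows)
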