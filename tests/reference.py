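"""Independent reference implementations used as test oracles.

Deliberately naive: plain-Python loops, formulas written from first
principles, no reuse of the package's classification or test machinery.
"""

import itertools
import math

import numpy as np


def oracle_classify(stream, velocity_threshold_deg_s=30.0, min_fixation_ms=60.0):
    """Brute-force I-VT reference: label every inter-sample interval
    independently, then merge maximal runs.

    Returns a list of dicts with kind/start/end (+ centroid or path).
    """
    t = stream.t_ms
    x, y = stream.x_px, stream.y_px
    valid = stream.valid
    geo = stream.geometry
    labels = []
    for i in range(len(t) - 1):
        if not (valid[i] and valid[i + 1]):
            labels.append("off")
            continue
        disp = math.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
        theta = math.degrees(
            2.0 * math.atan(disp * (geo.width_cm / geo.width_px) / (2.0 * geo.viewing_distance_cm))
        )
        vel = theta / ((t[i + 1] - t[i]) / 1000.0)
        labels.append("sac" if vel > velocity_threshold_deg_s else "sub")

    events = []
    i = 0
    while i < len(labels):
        j = i
        while j + 1 < len(labels) and labels[j + 1] == labels[i]:
            j += 1
        start, end = t[i], t[j + 1]
        if labels[i] == "off":
            events.append({"kind": "offscreen", "start": start, "end": end})
        elif labels[i] == "sac":
            path = sum(
                math.hypot(x[k + 1] - x[k], y[k + 1] - y[k]) for k in range(i, j + 1)
            )
            events.append({"kind": "saccade", "start": start, "end": end, "path": path})
        else:
            kind = "fixation" if (end - start) > min_fixation_ms else "microfixation"
            cx = float(np.mean(x[i : j + 2]))
            cy = float(np.mean(y[i : j + 2]))
            events.append({"kind": kind, "start": start, "end": end, "cx": cx, "cy": cy})
        i = j + 1
    return events


def mann_whitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u1(xs, ys):
        gt = sum(1 for a in xs for b in ys if a > b)
        eq = sum(1 for a in xs for b in ys if a == b)
        return gt + 0.5 * eq

    obs = u1(list(x), list(y))
    us = []
    idx_all = range(len(pooled))
    for chosen in itertools.combinations(idx_all, n1):
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx_all if i not in chosen]
        us.append(u1(xs, ys))
    us = np.asarray(us)
    p = 2.0 * min((us <= obs).mean(), (us >= obs).mean())
    return min(obs, n1 * len(y) - obs), min(1.0, p)
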