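"""Independent reference implementations used to check the LP solvers.

These are deliberately naive — geometric enumeration and O(s^2) pair loops —
and share no code with the package's production paths.
"""

from __future__ import annotations

import numpy as np


def vrs_theta_1d(x, y, q: int) -> float:
    """Radial score for the 1-input/1-output VRS model by hull enumeration.

    The maximal output attainable at input budget x_q is the upper concave,
    nondecreasing envelope of the observed points, which is achieved either
    at a single affordable point or on a segment between two points
    straddling x_q. Theta is that value divided by y_q.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xq, yq = x[q], y[q]
    best = -np.inf
    s = len(x)
    for i in range(s):
        if x[i] <= xq:
            best = max(best, y[i])
        for j in range(s):
            if x[i] < xq < x[j]:
                t = (xq - x[i]) / (x[j] - x[i])
                best = max(best, (1 - t) * y[i] + t * y[j])
    return best / yq


def crs_theta_1d(x, y, q: int) -> float:
    """Radial score for the 1-input/1-output CRS model: the best observed
    output/input ratio scaled to the query's ray."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(np.max(y / x) * x[q] / y[q])


def vrs_theta_grid(x, y, q: int, grid: int = 200) -> float:
    """Exhaustive simplex-grid search over lambda for tiny 1x1 instances
    (pairs of support points suffice at an LP vertex)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xq, yq = x[q], y[q]
    best = -np.inf
    s = len(x)
    ts = np.linspace(0.0, 1.0, grid + 1)
    for i in range(s):
        for j in range(s):
            lx = (1 - ts) * x[i] + ts * x[j]
            ly = (1 - ts) * y[i] + ts * y[j]
            ok = lx <= xq + 1e-12
            if np.any(ok):
                best = max(best, float(np.max(ly[ok])))
    return best / yq


def kendall_tau_a_brute(x, y) -> tuple[float, int, int, int]:
    """tau-a with explicit pair loops: concordant, discordant, tied counts;
    tied pairs only enter the denominator."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    s = len(x)
    c = d = t = 0
    for i in range(s):
        for j in range(i + 1, s):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 or dy == 0:
                t += 1
            elif (dx > 0) == (dy > 0):
                c += 1
            else:
                d += 1
    total = s * (s - 1) // 2
    return (c - d) / total, c, d, t
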