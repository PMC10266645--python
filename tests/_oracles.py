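"""Independent brute-force reference implementations used only by tests.

Each oracle is written in the most literal possible style (explicit loops,
no shared code with the package) so that agreement with the package is a
meaningful cross-check.
"""

import itertools
import math

import numpy as np


def pearson_scalar(a, b):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    den = math.sqrt(float(np.sum(am * am)) * float(np.sum(bm * bm)))
    if den == 0:
        return np.nan
    return float(np.sum(am * bm)) / den


def correlation_map_loop(values, y, kind, eps=1e-12):
    """Scalar double loop over ordered band pairs; NaN where undefined."""
    n, p = values.shape
    r = np.full((p, p), np.nan)
    for a in range(p):
        for b in range(p):
            ri, rj = values[:, a], values[:, b]
            if kind == "DI":
                idx = ri - rj
            elif kind == "RI":
                if a == b or np.any(np.abs(rj) < eps):
                    continue
                idx = ri / rj
            elif kind == "NDI":
                if a == b or np.any(np.abs(ri + rj) < eps):
                    continue
                idx = (ri - rj) / (ri + rj)
            if float(np.var(idx)) <= 1e-24:
                continue
            r[a, b] = pearson_scalar(idx, y)
    return r


def upper_hull_chords(wl, v):
    """Least concave majorant by exhaustive chord search.

    At each grid point the envelope equals the maximum, over every pair of
    points spanning it, of the chord value (every chord lies on or below the
    concave hull, and the hull itself is a chord between adjacent vertices).
    """
    wl = np.asarray(wl, float)
    v = np.asarray(v, float)
    p = wl.size
    env = np.array(v, copy=True)
    for k in range(p):
        for i in range(0, k + 1):
            for j in range(k, p):
                if i == j:
                    val = v[i]
                else:
                    t = (wl[k] - wl[i]) / (wl[j] - wl[i])
                    val = v[i] + t * (v[j] - v[i])
                env[k] = max(env[k], val)
    return env


def sg_center_fit(values, window, order):
    """Per-window polynomial least squares evaluated at the window center."""
    n, p = values.shape
    half = (window - 1) // 2
    out = np.empty((n, p - 2 * half))
    x = np.arange(-half, half + 1, dtype=float)
    for row in range(n):
        for c in range(half, p - half):
            coef = np.polyfit(x, values[row, c - half : c + half + 1], order)
            out[row, c - half] = np.polyval(coef, 0.0)
    return out


def kennard_stone_naive(x, n_cal):
    """Greedy max-min selection with explicit loops; ties to lower index."""
    x = np.asarray(x, float)
    n = x.shape[0]
    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(x[i] - x[j]))
            if d > best[0]:
                best = (d, (i, j))
    sel = list(best[1])
    while len(sel) < n_cal:
        cand, cand_d = None, -1.0
        for i in range(n):
            if i in sel:
                continue
            dmin = min(float(np.linalg.norm(x[i] - x[s])) for s in sel)
            if dmin > cand_d:
                cand, cand_d = i, dmin
        sel.append(cand)
    return sel


def rank_cells_exhaustive(bands, r_matrix, valid, kind, k):
    """Sort valid (deduplicated) cells by |r| then lexicographic bands."""
    cells = []
    p = len(bands)
    for a in range(p):
        for b in range(p):
            if not valid[a, b]:
                continue
            if kind in ("DI", "NDI") and a >= b:
                continue
            cells.append((-abs(r_matrix[a, b]), bands[a], bands[b], r_matrix[a, b]))
    cells.sort()
    return [(int(i), int(j), float(r)) for _, i, j, r in cells[:k]]
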