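"""Independent brute-force reference implementations used only by the tests.

Everything here is deliberately naive (scalar loops, all-pairs scans) and
shares no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def naive_gi_star(x, neighbor_lists, include_self):
    """Scalar, cell-by-cell evaluation of the Gi* display formula.

    ``neighbor_lists[i]`` holds the non-self neighbor positions of cell i.
    Returns (scores, degenerate) with NaN at degenerate cells.
    """
    x = np.asarray(x, float)
    n = len(x)
    xbar = sum(x) / n
    s = (sum(v * v for v in x) / n - xbar**2) ** 0.5
    scores = np.full(n, np.nan)
    degenerate = np.zeros(n, bool)
    for i in range(n):
        w = [0.0] * n
        for j in neighbor_lists[i]:
            w[j] = 1.0
        if include_self:
            w[i] = 1.0
        sw = sum(w)
        sw2 = sum(v * v for v in w)
        radical = (n * sw2 - sw**2) / (n - 1)
        if s == 0.0 or radical <= 0:
            degenerate[i] = True
            continue
        num = sum(w[j] * x[j] for j in range(n)) - xbar * sw
        scores[i] = num / (s * radical**0.5)
    return scores, degenerate


def brute_queen_adjacency(valid):
    """All-pairs queen adjacency over the valid cells of a boolean mask.

    Returns a dict position -> sorted list of neighbor positions, using the
    same row-major valid-cell ordering as the lattice module.
    """
    valid = np.asarray(valid, bool)
    n_rows, n_cols = valid.shape
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols) if valid[r, c]]
    pos = {rc: k for k, rc in enumerate(cells)}
    out = {k: [] for k in range(len(cells))}
    for (r1, c1), k1 in pos.items():
        for (r2, c2), k2 in pos.items():
            if k1 != k2 and abs(r1 - r2) <= 1 and abs(c1 - c2) <= 1:
                out[k1].append(k2)
    return {k: sorted(v) for k, v in out.items()}


def brute_moran(field2d, valid=None):
    """Global Moran's I by a double loop over queen-contiguous pairs."""
    field2d = np.asarray(field2d, float)
    n_rows, n_cols = field2d.shape
    if valid is None:
        valid = np.ones(field2d.shape, bool)
    cells = [(r, c) for r in range(n_rows) for c in range(n_cols) if valid[r, c]]
    vals = np.array([field2d[r, c] for r, c in cells])
    z = vals - vals.mean()
    num = 0.0
    w_total = 0
    index = {rc: i for i, rc in enumerate(cells)}
    for (r, c), i in index.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    num += z[i] * z[j]
                    w_total += 1
    return (len(cells) / w_total) * num / (z * z).sum()


def reference_trend_rule(c1, c2):
    """Restatement of the two-period taxonomy, straight from the definitions."""
    if c1 >= 5 and c2 >= 3:
        return "consistent"
    if c1 >= 3 and c2 <= 2:
        return "declining"
    if c1 <= 3 and c2 >= 4:
        return "emerging"
    return "inconsistent"
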