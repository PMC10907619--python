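"""Jenks natural-breaks classification.

Exact Fisher-style dynamic program minimizing total within-class sum of
squared deviations over contiguous classes of the sorted values —
deterministic given the data, O(n²·k).
"""

from __future__ import annotations

import numpy as np


def natural_breaks(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Optimal k-class breaks, reported as upper-inclusive bounds.

    Returns the k class maxima (the last one is the data maximum).
    Raises if the data have fewer distinct values than classes.
    """
    raw = np.asarray(values, float).ravel()
    raw = raw[np.isfinite(raw)]
    if k < 1:
        raise ValueError("k must be >= 1")
    # equal values always share a class under upper-inclusive breaks, so
    # the DP runs on unique values with multiplicities — this keeps huge
    # rasters with few distinct coefficients O(u²·k), u = n unique
    v, w = np.unique(raw, return_counts=True)
    n = v.size
    if n < k:
        raise ValueError("fewer distinct values than classes")
    w = w.astype(float)
    cs = np.concatenate([[0.0], np.cumsum(w * v)])
    cs2 = np.concatenate([[0.0], np.cumsum(w * v * v)])
    cn = np.concatenate([[0.0], np.cumsum(w)])

    def sse(i: int, j: int) -> float:
        # weighted SSE of the multiset spanning unique values v[i:j]
        m = cn[j] - cn[i]
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / m

    # cost[c][j]: minimal SSE partitioning v[:j] into c classes
    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                if cost[c - 1, i] == INF:
                    continue
                val = cost[c - 1, i] + sse(i, j)
                # ties broken toward the earlier cut (lower class kept small)
                if val < best - 1e-12:
                    best, arg = val, i
            cost[c, j] = best
            cut[c, j] = arg
    # backtrack class boundaries
    bounds = []
    j = n
    for c in range(k, 0, -1):
        bounds.append(j)
        j = cut[c, j]
    bounds = bounds[::-1]
    return np.array([v[b - 1] for b in bounds])


def classify(values: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Assign 1-based levels by upper-inclusive breaks; ties go low.

    NaNs (nodata) map to level 0.
    """
    arr = np.asarray(values, float)
    out = np.searchsorted(np.asarray(breaks)[:-1], arr, side="left") + 1
    out = np.minimum(out, len(breaks))
    out = np.where(np.isnan(arr), 0, out)
    return out.astype(int)
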