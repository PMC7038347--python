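"""Brute-force all-windows DTW oracle for validating the subsequence segmenter.

Independent route: for every window [s, j] of the signal, the classic
boundary-anchored DTW distance of the full template to that window is
computed from its own dynamic program; the best cost over all starts for
each end, the corresponding argmin start, and the same documented
local-minimum + ascending-cost greedy acceptance rule then yield the oracle
segmentation.  This is O(N²·M) and only meant for short signals.
"""

from __future__ import annotations

import numpy as np


def _window_dtw_rows(tmpl, sig):  # (M,), (N,) normalised 1-D arrays
    """best[j], start[j]: min over s of classicDTW(tmpl, sig[s:j+1])."""
    M = len(tmpl)
    N = len(sig)
    best = np.full(N, np.inf)
    start = np.zeros(N, np.int64)
    D = np.empty((M, N))
    for s in range(N):
        w = N - s
        D[0, 0] = abs(tmpl[0] - sig[s])
        for j in range(1, w):
            D[0, j] = D[0, j - 1] + abs(tmpl[0] - sig[s + j])
        for i in range(1, M):
            D[i, 0] = D[i - 1, 0] + abs(tmpl[i] - sig[s])
            for j in range(1, w):
                c = abs(tmpl[i] - sig[s + j])
                m = D[i - 1, j - 1]
                if D[i - 1, j] < m:
                    m = D[i - 1, j]
                if D[i, j - 1] < m:
                    m = D[i, j - 1]
                D[i, j] = c + m
        for j in range(w):
            cost = D[M - 1, j]
            if cost < best[s + j]:
                best[s + j] = cost
                start[s + j] = s
    return best, start


try:
    from numba import njit

    _window_dtw_rows = njit(cache=True)(_window_dtw_rows)
except Exception:  # pragma: no cover
    pass


def _local_minima(costs, threshold):
    """Leftmost indices of strict local minima at or below the threshold."""
    out = []
    n = len(costs)
    j = 0
    while j < n:
        k = j
        while k + 1 < n and costs[k + 1] == costs[j]:
            k += 1
        left = costs[j - 1] if j > 0 else np.inf
        right = costs[k + 1] if k + 1 < n else np.inf
        if costs[j] <= threshold and costs[j] < left and costs[j] < right:
            out.append(j)
        j = k + 1
    return out


def oracle_segments(signal, template_samples, threshold,
                    min_len=None, max_len=None):
    """Segments and costs from the brute-force all-windows route.

    Applies the same normalisation (template max-abs), candidate rule
    (local minima of the per-end best cost), length guards and greedy
    ascending-cost non-overlap acceptance as the production segmenter, but
    with costs and starts coming from exhaustive classic DTW per window.
    """
    tmpl = np.asarray(template_samples, dtype=float)
    scale = float(np.max(np.abs(tmpl))) or 1.0
    tmpl = np.ascontiguousarray(tmpl / scale)
    sig = np.ascontiguousarray(np.asarray(signal, dtype=float) / scale)
    m = len(tmpl)
    if min_len is None:
        min_len = max(2, m // 4)
    if max_len is None:
        max_len = 2 * m
    best, start = _window_dtw_rows(tmpl, sig)
    candidates = []
    for j in _local_minima(best, threshold):
        s, e = int(start[j]), j + 1
        if min_len <= e - s <= max_len:
            candidates.append((s, e, float(best[j])))
    accepted = []
    for s, e, c in sorted(candidates, key=lambda t: (t[2], t[0])):
        if all(e <= a or s >= b for a, b, _ in accepted):
            accepted.append((s, e, c))
    return sorted(accepted)
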