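"""Subsequence dynamic time warping stride segmentation.

Finds all non-overlapping subsequences of a long gyroscope-z signal whose
DTW distance to a stride template falls below a threshold.  The accumulated
cost matrix has template rows and signal columns; the first row is
initialised with local costs only, so a match may start at any column.  The
last row then holds, for every possible match end, the cost of the best
match ending there; local minima below the threshold are candidate strides,
each backtracked (via propagated start pointers) to its start column, and
candidates are accepted greedily in ascending cost order (ties toward the
leftmost), discarding any that overlap an accepted segment.

Local cost is the absolute difference on the (scale-normalised) signal; the
step pattern is the classic {(1,1), (1,0), (0,1)} set without weights.  Both
signal and template are divided by the template's max-absolute-value before
costing, so the acceptance threshold is scale-free.  Degenerate warps are
guarded by a minimum segment length of a quarter of the template length and
a maximum of twice the template length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SegmentationError
from .templates import StrideTemplate

#: Default acceptance threshold on the scale-normalised DTW cost, calibrated
#: on synthetic bouts of all three activities with sweep_threshold (the curve
#: is flat near its optimum, see docs/methods.md).  The historical value of
#: 65 stems from an unstated normalisation and is kept only as documentation.
DEFAULT_THRESHOLD = 25.0
LEGACY_THRESHOLD = 65.0


@dataclass
class SegmentationResult:
    """Sorted, pairwise non-overlapping candidate strides."""

    segments: list[tuple[int, int]]     # half-open [start, end) sample index
    costs: list[float]                  # DTW distance per segment
    threshold: float
    template_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = np.argsort([s for s, _ in self.segments]) if self.segments else []
        self.segments = [tuple(map(int, self.segments[i])) for i in order]
        self.costs = [float(self.costs[i]) for i in order]
        for (s0, e0), (s1, _e1) in zip(self.segments, self.segments[1:]):
            if s1 < e0:
                raise SegmentationError("segments overlap")

    def __len__(self) -> int:
        return len(self.segments)


# ---------------------------------------------------------------------------
# Accumulated-cost kernel (numba-accelerated when available)
# ---------------------------------------------------------------------------

def _subseq_lastrow(tmpl, sig):  # pragma: no cover - replaced by numba wrap
    """Last DP row and start pointers of the subsequence-DTW cost matrix.

    tmpl: (M, D), sig: (N, D).  Returns (costs (N,), starts (N,)): costs[j]
    is the accumulated cost of the best warp of the whole template onto a
    window ending at column j; starts[j] is that window's first column.
    Predecessor ties break diagonal > up > left.
    """
    M, D = tmpl.shape
    N = sig.shape[0]
    prev = np.empty(N)
    cur = np.empty(N)
    sprev = np.empty(N, np.int64)
    scur = np.empty(N, np.int64)
    for j in range(N):
        c = 0.0
        for d in range(D):
            c += abs(tmpl[0, d] - sig[j, d])
        prev[j] = c
        sprev[j] = j
    for i in range(1, M):
        c = 0.0
        for d in range(D):
            c += abs(tmpl[i, d] - sig[0, d])
        cur[0] = prev[0] + c
        scur[0] = 0
        for j in range(1, N):
            c = 0.0
            for d in range(D):
                c += abs(tmpl[i, d] - sig[j, d])
            diag = prev[j - 1]
            up = prev[j]
            left = cur[j - 1]
            if diag <= up and diag <= left:
                cur[j] = diag + c
                scur[j] = sprev[j - 1]
            elif up <= left:
                cur[j] = up + c
                scur[j] = sprev[j]
            else:
                cur[j] = left + c
                scur[j] = scur[j - 1]
        prev, cur = cur, prev
        sprev, scur = scur, sprev
    return prev.copy(), sprev.copy()


try:  # optional speedup; the pure-Python kernel is the reference behaviour
    from numba import njit

    _subseq_lastrow_jit = njit(cache=True)(_subseq_lastrow)
except Exception:  # pragma: no cover
    _subseq_lastrow_jit = _subseq_lastrow


def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return np.ascontiguousarray(x)


def _local_minima(costs: np.ndarray, threshold: float) -> list[int]:
    """Indices of strict local minima (plateaus collapse to their leftmost
    index) with cost at or below the threshold."""
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


def _greedy_select(candidates: Sequence[tuple[int, int, float]]):
    """Accept candidates in ascending (cost, start) order, skipping overlaps."""
    accepted: list[tuple[int, int, float]] = []
    for start, end, cost in sorted(candidates, key=lambda c: (c[2], c[0])):
        if all(end <= a or start >= b for a, b, _ in accepted):
            accepted.append((start, end, cost))
    return sorted(accepted)


def subsequence_dtw(
    signal,
    template: StrideTemplate | np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int | None = None,
    max_len: int | None = None,
) -> SegmentationResult:
    """Segment a signal into template-like subsequences.

    ``signal`` is the gyroscope-z trace (deg/s) — or an (N, D) array, in
    which case local costs are summed over dimensions.  ``template`` is a
    :class:`StrideTemplate` or a raw waveform.
    """
    if isinstance(template, StrideTemplate):
        tmpl_arr = template.samples
        scale = template.scale
        template_id = template.activity
    else:
        tmpl_arr = np.asarray(template, dtype=float)
        scale = float(np.max(np.abs(tmpl_arr))) or 1.0
        template_id = "array"
    tmpl = _as_2d(tmpl_arr) / scale
    sig = _as_2d(signal) / scale
    m, n = len(tmpl), len(sig)
    if n < m / 4:
        raise SegmentationError(
            f"signal of {n} samples shorter than template_length/4 = {m / 4:.0f}"
        )
    if min_len is None:
        min_len = max(2, m // 4)
    if max_len is None:
        max_len = 2 * m

    costs, starts = _subseq_lastrow_jit(tmpl, sig)
    candidates = []
    for j in _local_minima(costs, threshold):
        start, end = int(starts[j]), j + 1
        if min_len <= end - start <= max_len:
            candidates.append((start, end, float(costs[j])))
    accepted = _greedy_select(candidates)
    return SegmentationResult(
        segments=[(s, e) for s, e, _ in accepted],
        costs=[c for _, _, c in accepted],
        threshold=float(threshold),
        template_id=template_id,
    )


# ---------------------------------------------------------------------------
# Threshold sweep
# ---------------------------------------------------------------------------

def match_segments_to_strides(
    segments: Sequence[tuple[int, int]],
    truth_bounds: Sequence[tuple[int, int]],
    min_overlap: float = 0.5,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching by overlap fraction of the truth stride.

    A stride counts as found when a segment overlaps at least ``min_overlap``
    of it.  Returns (tp, fp, fn).
    """
    pairs = []
    for si, (s0, s1) in enumerate(segments):
        for ti, (t0, t1) in enumerate(truth_bounds):
            ov = min(s1, t1) - max(s0, t0)
            frac = ov / (t1 - t0) if t1 > t0 else 0.0
            if frac >= min_overlap:
                pairs.append((-frac, si, ti))
    used_s, used_t = set(), set()
    tp = 0
    for _negfrac, si, ti in sorted(pairs):
        if si in used_s or ti in used_t:
            continue
        used_s.add(si)
        used_t.add(ti)
        tp += 1
    fp = len(segments) - tp
    fn = len(truth_bounds) - tp
    return tp, fp, fn


def f_score(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def sweep_threshold(
    signal,
    truth_bounds,
    template: StrideTemplate | np.ndarray,
    grid: Sequence[float] | None = None,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Segmentation F-score as a function of the acceptance threshold.

    The default grid runs from 0 to 100 in steps of 5.  Returns the raw
    curve (threshold, tp, fp, fn, f_score); no unimodality is assumed.
    """
    if grid is None:
        grid = np.arange(0.0, 100.0 + 1e-9, 5.0)
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    rows = []
    for thr in grid:
        res = subsequence_dtw(signal, template, threshold=thr)
        tp, fp, fn = match_segments_to_strides(res.segments, truth_bounds,
                                               min_overlap)
        rows.append({"threshold": float(thr), "tp": tp, "fp": fp, "fn": fn,
                     "f_score": f_score(tp, fp, fn)})
    return pd.DataFrame(rows)


def best_threshold(sweep: pd.DataFrame) -> float:
    """Grid value maximising the F-score (ties toward the smaller threshold)."""
    return float(sweep.loc[sweep["f_score"].idxmax(), "threshold"])
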