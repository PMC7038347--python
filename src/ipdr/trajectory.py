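"""Stride-level trajectory assembly and evaluation metrics.

The trajectory of a bout is the sequence of planar foot positions at the
Mid-Stance events.  The stride length of stride k is the planar norm of the
position increment from the previous Mid-Stance:

    SL_k = sqrt(∇P_k(x)² + ∇P_k(y)²)

(the vertical component is ignored — on level indoor floors it carries only
integration residue).  The stride heading is the atan2 of the increment.

Evaluation metrics:

* event F-score — a detected event is a true positive when it lies within a
  tolerance of ±15% of the stride's sample count around a ground-truth
  event (one-to-one, greedy nearest-first matching); F = 2TP/(2TP+FP+FN).
* return position error (RPE) — planar distance between the reconstructed
  final stride position and the known endpoint of a closed-loop trial,
  absolute and as a percentage of the total path length.
* strides out of trajectory (SOT) — count/fraction of stride positions
  falling outside the union of user-supplied corridor polygons (boundary
  counts as inside).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .errors import DataError


@dataclass
class Trajectory:
    """Per-stride planar positions at Mid-Stance, lengths and headings."""

    stride_positions: np.ndarray       # (K, 2) m
    start_position: np.ndarray         # (2,) m
    stride_lengths: np.ndarray = field(init=False)
    headings_deg: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.stride_positions = np.asarray(self.stride_positions,
                                           dtype=float).reshape(-1, 2)
        self.start_position = np.asarray(self.start_position,
                                         dtype=float).reshape(2)
        prev = np.vstack([self.start_position, self.stride_positions[:-1]])
        inc = self.stride_positions - prev
        self.stride_lengths = np.hypot(inc[:, 0], inc[:, 1])
        self.headings_deg = np.degrees(np.arctan2(inc[:, 1], inc[:, 0]))

    @property
    def n_strides(self) -> int:
        return len(self.stride_positions)

    @property
    def total_distance(self) -> float:
        return float(self.stride_lengths.sum())

    @property
    def end_position(self) -> np.ndarray:
        return self.stride_positions[-1] if self.n_strides else self.start_position


def stride_length(p_prev, p_curr) -> float:
    """Planar norm of the position increment; the z component is ignored."""
    d = np.asarray(p_curr, dtype=float) - np.asarray(p_prev, dtype=float)
    return float(np.hypot(d[0], d[1]))


def trajectory_from_states(positions: np.ndarray, ms_indices) -> Trajectory:
    """Sample the navigation solution at the Mid-Stance instants."""
    ms = np.asarray(ms_indices, dtype=int)
    if ms.size == 0:
        raise DataError("no Mid-Stance events to build a trajectory from")
    return Trajectory(stride_positions=positions[ms, :2],
                      start_position=positions[0, :2])


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Event-detection counts and derived scores."""

    tp: int
    fp: int
    fn: int

    @property
    def f_score(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "f_score": self.f_score}


def score_events(
    detected: Sequence[int],
    truth: Sequence[int],
    stride_bounds: Sequence[tuple[int, int]],
    tolerance_frac: float = 0.15,
) -> EvalReport:
    """Greedy nearest-first one-to-one matching at a per-stride tolerance.

    Each ground-truth event belongs to a stride; a detection within
    ``tolerance_frac`` of that stride's sample count (to either side)
    may match it.  Unmatched detections are false positives, unmatched
    truths false negatives.
    """
    bounds = [tuple(map(int, b)) for b in stride_bounds]
    for (s0, e0), (s1, _e1) in zip(sorted(bounds), sorted(bounds)[1:]):
        if s1 < e0:
            raise DataError("stride bounds overlap")
    if len(truth) != len(bounds):
        raise DataError("each ground-truth event needs its stride bounds")
    detected = np.asarray(sorted(detected), dtype=int)
    pairs = []
    for ti, (t, (s0, e0)) in enumerate(zip(truth, bounds)):
        tol = tolerance_frac * (e0 - s0)
        for di, d in enumerate(detected):
            dist = abs(int(d) - int(t))
            if dist <= tol:
                pairs.append((dist, ti, di))
    used_t, used_d = set(), set()
    tp = 0
    for _dist, ti, di in sorted(pairs):
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        tp += 1
    return EvalReport(tp=tp, fp=len(detected) - tp, fn=len(truth) - tp)


def return_position_error(
    traj: Trajectory, end_truth=(0.0, 0.0)
) -> tuple[float, float | None]:
    """Distance between the final stride position and the true endpoint.

    Returns (metres, percent of total path distance); the percentage is
    None when the total distance is zero.
    """
    end_truth = np.asarray(end_truth, dtype=float).reshape(-1)[:2]
    rpe = float(np.linalg.norm(traj.end_position - end_truth))
    total = traj.total_distance
    return rpe, (100.0 * rpe / total if total > 0 else None)


def strides_out_of_trajectory(
    traj: Trajectory, zones: Sequence
) -> tuple[int, float]:
    """Strides whose Mid-Stance position lies outside every corridor zone.

    ``zones`` is a list of polygons (vertex lists or shapely Polygons).
    A point on a zone boundary counts as inside.
    """
    polys = []
    for z in zones:
        poly = z if isinstance(z, Polygon) else Polygon(z)
        if not poly.is_valid:
            raise DataError("zone polygon is invalid (self-intersecting?)")
        polys.append(poly)
    out = 0
    for x, y in traj.stride_positions:
        pt = Point(float(x), float(y))
        if not any(poly.covers(pt) for poly in polys):
            out += 1
    pct = 100.0 * out / traj.n_strides if traj.n_strides else 0.0
    return out, pct


def load_zones(path: str | Path) -> list[Polygon]:
    """Zones file: JSON list of polygons, each a list of [x, y] vertices."""
    data = json.loads(Path(path).read_text())
    return [Polygon(v) for v in data]
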