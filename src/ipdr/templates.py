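"""Per-activity stride templates: interpolation and sample-wise averaging.

A stride template is the gyroscope-z waveform of one canonical stride,
resampled to a fixed duration of 200 samples.  Templates are built from a
set of labelled strides: each stride is linearly interpolated onto the
200-sample grid and the template is the sample-wise mean.  By the stride
boundary convention (negative dip before the swing phase to the negative
dip of the next stride) a well-formed template begins and ends in
negative-valued regions.

Templates are stored un-normalised in deg/s.  A per-template ``scale`` (its
maximum absolute value) is recorded; the segmenter divides both signal and
template by this scale so that its acceptance threshold is scale-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from .errors import SegmentationError

TEMPLATE_LENGTH = 200


@dataclass
class StrideTemplate:
    """200-sample gyroscope-z reference waveform for one activity class."""

    activity: str
    samples: np.ndarray                 # (200,) deg/s
    n_source_strides: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)
        if len(self.samples) != TEMPLATE_LENGTH:
            raise ValueError(
                f"template must have exactly {TEMPLATE_LENGTH} samples, "
                f"got {len(self.samples)}"
            )

    @property
    def scale(self) -> float:
        """Normalisation constant used at match time (max absolute value)."""
        return float(np.max(np.abs(self.samples)))

    # -- persistence --------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "activity": self.activity,
            "samples": self.samples.tolist(),
            "n_source_strides": self.n_source_strides,
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "StrideTemplate":
        d = json.loads(Path(path).read_text())
        return cls(activity=d["activity"], samples=np.array(d["samples"]),
                   n_source_strides=d.get("n_source_strides", 1),
                   meta=d.get("meta", {}))


def interpolate_stride(stride, n: int = TEMPLATE_LENGTH) -> np.ndarray:
    """Linearly interpolate a stride onto ``n`` equally spaced points.

    The grid spans the full stride, so the endpoints are preserved exactly
    and an input already of length ``n`` comes back unchanged.
    """
    stride = np.asarray(stride, dtype=float)
    if stride.ndim != 1:
        raise SegmentationError("stride must be one-dimensional")
    m = len(stride)
    if m < 4:
        raise SegmentationError(f"stride of {m} samples is too short (< 4)")
    if m == n:
        return stride.copy()
    return np.interp(np.linspace(0.0, m - 1.0, n), np.arange(m), stride)


def build_template(strides, activity: str, meta: dict | None = None) -> StrideTemplate:
    """Sample-wise average of interpolated strides."""
    strides = list(strides)
    if not strides:
        raise ValueError("cannot build a template from zero strides")
    grid = np.stack([interpolate_stride(s) for s in strides])
    return StrideTemplate(
        activity=activity,
        samples=grid.mean(axis=0),
        n_source_strides=len(strides),
        meta=meta or {},
    )


def strides_from_ground_truth(signal: np.ndarray, stride_bounds) -> list[np.ndarray]:
    """Cut a gyroscope-z signal into strides at known boundaries."""
    return [signal[int(s):int(e)] for s, e in stride_bounds]


@lru_cache(maxsize=8)
def default_template(activity: str, rate_hz: float = 200.0,
                     n_strides: int = 20, seed: int = 0) -> StrideTemplate:
    """Template generated from the synthetic gait model.

    Shipped defaults are synthetic: a noise-free bout of ``n_strides``
    strides is generated, cut at ground-truth stride boundaries and
    averaged.  Users with labelled real strides should build their own
    templates with :func:`build_template`.
    """
    from .synthetic_gait import GaitPlan, NoiseModel, plan_trajectory, synthesize_imu

    plan = GaitPlan(activity=activity, n_strides=n_strides, rate_hz=rate_hz,
                    lead_in_s=2.0, lead_out_s=1.0)
    gt = plan_trajectory(plan)
    seq = synthesize_imu(gt, NoiseModel.zero())
    strides = strides_from_ground_truth(seq.gyr[:, 2], gt.stride_bounds)
    return build_template(
        strides, activity,
        meta={"synthetic": True, "n_strides": n_strides, "seed": seed},
    )
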