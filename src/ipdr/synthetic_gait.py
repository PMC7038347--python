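"""Synthetic foot-mounted IMU signals with full ground truth.

The generator works "inverse strapdown": it first lays down a kinematically
exact foot trajectory (position + attitude per sample) for a planned sequence
of strides, then differentiates it into body-frame gyroscope and specific
force.  Because the velocities handed out as ground truth are the forward
differences of the positions, a first-order strapdown integrator fed the
noise-free signals reproduces the trajectory to machine precision — this
round trip is the foundation of the test suite.

Stride model
------------
Each stride is a swing phase followed by a stance phase.  During stance the
foot is flat on the ground: position constant, pitch constant, velocity
exactly zero.  During swing (fraction ``1 - stance_fraction`` of the stride):

* forward displacement follows an integrated raised-cosine velocity profile
  (zero velocity at both ends, C¹ junction with stance),
* vertical lift is a raised-cosine bump,
* sagittal foot pitch follows a smooth profile whose *rate* — the gyroscope
  z-axis — has the canonical stride morphology: a negative valley after the
  foot leaves the ground... more precisely a negative dip at the start of
  swing, a large positive peak at mid-swing, and a negative dip before heel
  strike, with zero net pitch per stride.

With the swing angular-rate shape ``r(τ) ∝ -sin²(πτ)·(cos 2πτ + ½)`` the
zero-crossing before the positive peak sits at τ = 1/3 of the swing; that
crossing is the ground-truth Toe-Off.  Heel-Strike is the first stance
sample and Mid-Stance the centre of the stance window.

Stride boundaries for segmentation purposes run from the negative swing dip
of one stride to the negative swing dip of the next, so extracted strides
begin and end in negative-valued gyroscope-z regions — the template
convention used by the stride segmenter.

Activity defaults: walking strides last ~1 s with a stance phase of ~60% of
the stride; jogging and running strides are shorter with ~40% stance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import PlanError
from .imu_core import GRAVITY, IMUSequence

__all__ = [
    "GaitPlan", "GroundTruth", "NoiseModel",
    "plan_trajectory", "synthesize_imu", "ACTIVITY_DEFAULTS",
]

#: Per-activity stride defaults: duration (s), length (m), stance fraction,
#: swing foot lift (m).  Walking strides last around one second with ~60%
#: stance; jogging/running stance shrinks to ~40%.
ACTIVITY_DEFAULTS = {
    "walk": dict(stride_time_s=1.0, stride_length_m=1.4,
                 stance_fraction=0.6, foot_lift_m=0.15,
                 pitch_amplitude_deg=35.0),
    "jog": dict(stride_time_s=0.8, stride_length_m=2.0,
                stance_fraction=0.4, foot_lift_m=0.25,
                pitch_amplitude_deg=55.0),
    "run": dict(stride_time_s=0.7, stride_length_m=2.4,
                stance_fraction=0.4, foot_lift_m=0.30,
                pitch_amplitude_deg=70.0),
}


@dataclass
class GaitPlan:
    """Deterministic description of a gait bout.

    ``stride_length_m``, ``stride_time_s`` and ``heading_deg`` may be scalars
    (applied to every stride) or per-stride arrays of length ``n_strides``.
    ``lead_in_s``/``lead_out_s`` are standing-still intervals framing the
    bout; the lead-in doubles as the gyroscope-bias calibration window.
    """

    activity: str
    n_strides: int
    stride_length_m: float | Sequence[float] | None = None
    stride_time_s: float | Sequence[float] | None = None
    stance_fraction: float | None = None
    heading_deg: float | Sequence[float] = 0.0
    rate_hz: float = 200.0
    lead_in_s: float = 10.0
    lead_out_s: float = 2.0
    pitch_amplitude_deg: float | None = None
    stance_dip_deg: float = 4.0
    foot_lift_m: float | None = None
    jitter_frac: float = 0.0
    jitter_seed: int = 0

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITY_DEFAULTS:
            raise PlanError(f"unknown activity '{self.activity}'")
        d = ACTIVITY_DEFAULTS[self.activity]
        if self.stride_length_m is None:
            self.stride_length_m = d["stride_length_m"]
        if self.stride_time_s is None:
            self.stride_time_s = d["stride_time_s"]
        if self.stance_fraction is None:
            self.stance_fraction = d["stance_fraction"]
        if self.foot_lift_m is None:
            self.foot_lift_m = d["foot_lift_m"]
        if self.pitch_amplitude_deg is None:
            self.pitch_amplitude_deg = d["pitch_amplitude_deg"]
        if not (0.1 < self.stance_fraction < 0.8):
            raise PlanError(
                f"stance_fraction {self.stance_fraction} outside (0.1, 0.8)"
            )
        if self.n_strides < 1:
            raise PlanError("need at least one stride")

    # -- per-stride vectors -------------------------------------------------
    def _per_stride(self, value, name) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float),
                              (self.n_strides,)).copy()
        return arr

    def stride_lengths(self) -> np.ndarray:
        arr = self._per_stride(self.stride_length_m, "stride_length_m")
        return self._jitter(arr, 0)

    def stride_times(self) -> np.ndarray:
        arr = self._per_stride(self.stride_time_s, "stride_time_s")
        arr = self._jitter(arr, 1)
        if np.any(arr * self.rate_hz < 40):
            raise PlanError("stride_time_s * rate_hz must be >= 40 samples")
        return arr

    def headings(self) -> np.ndarray:
        return self._per_stride(self.heading_deg, "heading_deg")

    def _jitter(self, arr: np.ndarray, salt: int) -> np.ndarray:
        if self.jitter_frac <= 0:
            return arr
        rng = np.random.default_rng(self.jitter_seed + salt)
        return arr * (1.0 + self.jitter_frac * rng.uniform(-1, 1, len(arr)))

    # -- factories ----------------------------------------------------------
    @classmethod
    def straight(cls, activity: str, n_strides: int, **kw) -> "GaitPlan":
        return cls(activity=activity, n_strides=n_strides, **kw)

    @classmethod
    def square_loop(cls, activity: str, strides_per_side: int, **kw) -> "GaitPlan":
        """Closed square path: four sides with 90° left turns.

        Closure is exact by construction (equal and opposite side vectors).
        """
        headings = np.repeat([0.0, 90.0, 180.0, 270.0], strides_per_side)
        return cls(activity=activity, n_strides=4 * strides_per_side,
                   heading_deg=headings, **kw)


@dataclass
class NoiseModel:
    """Additive white sensor noise plus a constant gyroscope bias.

    Defaults are the study conditions used throughout the test bed:
    accelerometer noise 0.05 m/s², gyroscope noise 0.2 deg/s and a constant
    gyroscope bias of 0.5 deg/s per axis — a realistic consumer-grade MEMS
    budget at 200 Hz.
    """

    acc_noise_std: float = 0.05          # m/s²
    gyr_noise_std: float = 0.2           # deg/s
    gyr_bias: Sequence[float] = (0.5, 0.5, 0.5)   # deg/s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.acc_noise_std < 0 or self.gyr_noise_std < 0:
            raise PlanError("noise stds must be >= 0")
        self.gyr_bias = np.broadcast_to(
            np.asarray(self.gyr_bias, dtype=float), (3,)).copy()

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(acc_noise_std=0.0, gyr_noise_std=0.0, gyr_bias=(0, 0, 0))


@dataclass
class GroundTruth:
    """Per-sample truth for a generated bout plus per-stride event indices."""

    positions: np.ndarray        # (N, 3) m, navigation frame (ENU, z up)
    velocities: np.ndarray       # (N, 3) m/s (forward differences)
    attitude: np.ndarray         # (N, 3, 3) body→nav rotation matrices
    to_indices: np.ndarray       # (K,) sample index of Toe-Off per stride
    hs_indices: np.ndarray       # (K,) Heel-Strike (first stance sample)
    ms_indices: np.ndarray       # (K,) Mid-Stance (centre of stance)
    zv_mask: np.ndarray          # (N,) bool, true where foot velocity is zero
    stride_bounds: np.ndarray    # (K, 2) half-open [start, end), dip-to-dip
    rate_hz: float
    meta: dict = field(default_factory=dict)

    @property
    def n_strides(self) -> int:
        return len(self.to_indices)

    @property
    def path_length_m(self) -> float:
        return float(self.meta.get("path_length_m", np.nan))


# ---------------------------------------------------------------------------
# Swing-phase shape functions (τ in [0, 1])
# ---------------------------------------------------------------------------

def _swing_pitch(tau: np.ndarray) -> np.ndarray:
    """Unit pitch-angle profile; returns to 0 at τ=1 (zero net rotation).

    Antiderivative of -sin²(πτ)(cos 2πτ + ½):  θ(τ) = -(2 sin 2πτ - sin 4πτ)/(16π).
    """
    return -(2.0 * np.sin(2 * np.pi * tau) - np.sin(4 * np.pi * tau)) / (16 * np.pi)


#: max |_swing_pitch| over [0,1], attained at τ = 1/3:  3√3/(32π)
_PITCH_UNIT_MAX = 3.0 * np.sqrt(3.0) / (32.0 * np.pi)


def _swing_forward(tau: np.ndarray) -> np.ndarray:
    """Unit forward displacement: integrated raised-cosine velocity."""
    return tau - np.sin(2 * np.pi * tau) / (2 * np.pi)


def _swing_lift(tau: np.ndarray) -> np.ndarray:
    """Unit vertical lift: raised-cosine bump, zero at both ends."""
    return 0.5 * (1.0 - np.cos(2 * np.pi * tau))


def _blend(tau: np.ndarray) -> np.ndarray:
    """Raised-cosine 0→1 blend used for heading transitions."""
    return 0.5 * (1.0 - np.cos(np.pi * tau))


#: stance fractions occupied by the loading-response and pre-swing pitch dips
_STANCE_DIP_FRACS = (0.25, 0.2)


def _stance_pitch(u: np.ndarray, dip_rad: float) -> np.ndarray:
    """Small zero-net pitch dips at the stance edges (u = stance fraction).

    After heel strike the foot rotates briefly into foot-flat (loading
    response) and rotates again just before the next toe-off (pre-swing);
    mid-stance between them is rotationally quiet — this is the structure
    that makes the minimum-energy window criterion identify Mid-Stance.
    The foot's *position* stays fixed throughout (rotation about the sensor
    point), so stance remains a true zero-velocity interval.
    """
    e1, e2 = _STANCE_DIP_FRACS
    pitch = np.zeros_like(u)
    head = u < e1
    pitch[head] = -dip_rad * np.sin(np.pi * u[head] / e1) ** 2
    tail = u >= 1.0 - e2
    pitch[tail] = -dip_rad * np.sin(np.pi * (u[tail] - (1.0 - e2)) / e2) ** 2
    return pitch


def _attitude_matrices(yaw_rad: np.ndarray, pitch_rad: np.ndarray) -> np.ndarray:
    """Body→nav rotations for a foot with body axes x-forward, y-up, z-right.

    Level pose with heading ψ (from nav-x, CCW): forward b1 = (cosψ, sinψ, 0),
    up b2 = (0,0,1), lateral b3 = b1×b2 = (sinψ, -cosψ, 0).  Sagittal pitch θ
    rotates b1, b2 about b3 (θ>0 pitches the toe up), so gyroscope-z is the
    sagittal pitch rate.
    """
    cy, sy = np.cos(yaw_rad), np.sin(yaw_rad)
    cp, sp = np.cos(pitch_rad), np.sin(pitch_rad)
    n = len(yaw_rad)
    C = np.empty((n, 3, 3))
    b1 = np.stack([cy, sy, np.zeros(n)], axis=1)
    b2 = np.stack([np.zeros(n), np.zeros(n), np.ones(n)], axis=1)
    b3 = np.stack([sy, -cy, np.zeros(n)], axis=1)
    C[:, :, 0] = cp[:, None] * b1 + sp[:, None] * b2
    C[:, :, 1] = cp[:, None] * b2 - sp[:, None] * b1
    C[:, :, 2] = b3
    return C


# ---------------------------------------------------------------------------
# Trajectory planning
# ---------------------------------------------------------------------------

def plan_trajectory(plan: GaitPlan) -> GroundTruth:
    """Lay down the exact foot trajectory and ground-truth events for a plan."""
    rate = plan.rate_hz
    dt = 1.0 / rate
    lengths = plan.stride_lengths()
    times = plan.stride_times()
    headings = np.deg2rad(plan.headings())
    amp = np.deg2rad(plan.pitch_amplitude_deg) / _PITCH_UNIT_MAX

    n_lead = int(round(plan.lead_in_s * rate))
    n_out = int(round(plan.lead_out_s * rate))

    pos_chunks = [np.tile([0.0, 0.0, 0.0], (n_lead, 1))]
    yaw_chunks = [np.full(n_lead, headings[0])]
    pitch_chunks = [np.zeros(n_lead)]
    zv_chunks = [np.ones(n_lead, dtype=bool)]

    cursor = n_lead                     # global sample index of next chunk
    p0 = np.zeros(3)                    # foot position at start of stride
    prev_yaw = headings[0]
    to_idx, hs_idx, ms_idx, dip_idx = [], [], [], []
    stance_ends = []

    for k in range(plan.n_strides):
        n_k = int(round(times[k] * rate))
        n_swing = int(round((1.0 - plan.stance_fraction) * n_k))
        n_stance = n_k - n_swing
        if n_swing < 12 or n_stance < 4:
            raise PlanError(
                f"stride {k}: swing {n_swing}/stance {n_stance} samples too "
                f"short at rate {rate} Hz"
            )
        tau = np.arange(n_swing) / n_swing          # swing samples, τ ∈ [0, 1)
        yaw_k = prev_yaw + _wrap_angle(headings[k] - prev_yaw) * _blend(tau)
        pitch_k = amp * _swing_pitch(tau)
        direction = np.array([np.cos(headings[k]), np.sin(headings[k]), 0.0])
        swing_pos = (p0[None, :]
                     + lengths[k] * _swing_forward(tau)[:, None] * direction[None, :])
        swing_pos[:, 2] += plan.foot_lift_m * _swing_lift(tau)
        p1 = p0 + lengths[k] * direction

        pos_chunks.append(swing_pos)
        yaw_chunks.append(yaw_k)
        pitch_chunks.append(pitch_k)
        zv_chunks.append(np.zeros(n_swing, dtype=bool))

        pos_chunks.append(np.tile(p1, (n_stance, 1)))
        yaw_chunks.append(np.full(n_stance, headings[k]))
        pitch_chunks.append(_stance_pitch(np.arange(n_stance) / n_stance,
                                          np.deg2rad(plan.stance_dip_deg)))
        zv_chunks.append(np.ones(n_stance, dtype=bool))

        # Ground-truth events, in global sample indices.
        rate_profile = np.diff(_swing_pitch(np.arange(n_swing + 1) / n_swing))
        first_lobe = rate_profile[: n_swing // 2]
        dip = cursor + int(np.argmin(first_lobe))
        # Toe-Off: first swing sample with positive pitch rate (the sampled
        # zero-crossing before the mid-swing peak, at τ ≈ 1/3).
        to = cursor + int(np.argmax(rate_profile > 0))
        hs = cursor + n_swing                       # first stance sample
        ms = hs + n_stance // 2                     # centre of stance
        dip_idx.append(dip)
        to_idx.append(to)
        hs_idx.append(hs)
        ms_idx.append(ms)
        stance_ends.append(cursor + n_k)

        cursor += n_k
        p0 = p1
        prev_yaw = headings[k]

    pos_chunks.append(np.tile(p0, (n_out, 1)))
    yaw_chunks.append(np.full(n_out, prev_yaw))
    pitch_chunks.append(np.zeros(n_out))
    zv_chunks.append(np.ones(n_out, dtype=bool))

    positions = np.concatenate(pos_chunks, axis=0)
    yaw = np.concatenate(yaw_chunks)
    pitch = np.concatenate(pitch_chunks)
    zv = np.concatenate(zv_chunks)
    n = len(positions)

    # Forward-difference velocities keep the strapdown round trip exact.
    velocities = np.zeros_like(positions)
    velocities[:-1] = np.diff(positions, axis=0) * rate
    # Trim each zero-velocity run by its last sample: the forward difference
    # there straddles the first (tiny) swing displacement.
    zv_trim = zv & (np.linalg.norm(velocities, axis=1) < 1e-9)

    attitude = _attitude_matrices(yaw, pitch)
    bounds = np.column_stack([dip_idx, np.append(dip_idx[1:], stance_ends[-1])])

    meta = {
        "activity": plan.activity,
        "path_length_m": float(lengths.sum()),
        "rate_hz": rate,
        "n_strides": plan.n_strides,
        "lead_in_samples": n_lead,
    }
    return GroundTruth(
        positions=positions, velocities=velocities, attitude=attitude,
        to_indices=np.array(to_idx), hs_indices=np.array(hs_idx),
        ms_indices=np.array(ms_idx), zv_mask=zv_trim,
        stride_bounds=bounds, rate_hz=rate, meta=meta,
    )


def _wrap_angle(a: float) -> float:
    """Wrap to (-π, π] so heading blends take the short way round."""
    return (a + np.pi) % (2 * np.pi) - np.pi


# ---------------------------------------------------------------------------
# Inverse strapdown
# ---------------------------------------------------------------------------

def synthesize_imu(
    gt: GroundTruth,
    noise: NoiseModel | None = None,
    rate_hz: float | None = None,
) -> IMUSequence:
    """Differentiate a ground-truth trajectory into body-frame IMU signals.

    The discretisation mirrors the first-order strapdown integrator exactly:

    * gyroscope[k] = log(C_kᵀ C_{k+1}) / dt (body-frame rotation vector rate),
    * specific force[k] = C_kᵀ ((v_{k+1} − v_k)/dt + (0, 0, g)),

    so integrating the noise-free output reproduces positions to machine
    precision.  Noise and bias from the NoiseModel are then added; the same
    seed yields bitwise-identical output.
    """
    if noise is None:
        noise = NoiseModel.zero()
    rate = rate_hz or gt.rate_hz
    dt = 1.0 / rate
    n = len(gt.positions)

    R = Rotation.from_matrix(gt.attitude)
    rel = R[:-1].inv() * R[1:]
    omega_body = rel.as_rotvec() / dt            # rad/s, (n-1, 3)
    omega_body = np.vstack([omega_body, omega_body[-1]])

    a_nav = np.zeros((n, 3))
    a_nav[:-1] = np.diff(gt.velocities, axis=0) / dt
    f_nav = a_nav + np.array([0.0, 0.0, GRAVITY])
    f_body = np.einsum("nij,nj->ni", gt.attitude.transpose(0, 2, 1), f_nav)

    rng = np.random.default_rng(noise.seed)
    acc = f_body + rng.normal(0.0, noise.acc_noise_std or 0.0, (n, 3)) \
        if noise.acc_noise_std > 0 else f_body.copy()
    gyr = np.rad2deg(omega_body) + noise.gyr_bias
    if noise.gyr_noise_std > 0:
        gyr = gyr + rng.normal(0.0, noise.gyr_noise_std, (n, 3))

    meta = dict(gt.meta) | {"synthetic": True, "noise_seed": noise.seed}
    return IMUSequence(t=np.arange(n) / rate, acc=acc, gyr=gyr,
                       rate_hz=rate, meta=meta)
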