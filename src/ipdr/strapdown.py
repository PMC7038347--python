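"""Strapdown inertial navigation with zero-velocity updates.

Propagation is the classic first-order strapdown loop at the IMU rate:
the attitude matrix is advanced with the exact Rodrigues exponential of the
gyroscope increment, the specific force is rotated into the navigation
frame (ENU, z up), gravity is removed, and velocity and position are
integrated rectangularly (position with the pre-update velocity).

Drift is arrested with zero-velocity updates (ZUPT): whenever the foot is
known to be on the ground its true velocity is zero, so the strapdown
velocity estimate *is* the velocity error.  A 9-state error-state
(complementary) Kalman filter — attitude error φ, velocity error δv,
position error δp, all in the navigation frame — propagates the error
covariance alongside the strapdown solution and, at every zero-velocity
sample, takes the estimated velocity as a measurement of δv, feeds the
posterior error back into the states and resets the error to zero.  The
formulation follows the standard foot-mounted ZUPT tutorial filter: the
attitude error couples into velocity error through the skew of the
navigation-frame specific force; process noise enters from the gyroscope
(attitude) and accelerometer (velocity) white-noise densities.

Zero-velocity detection is activity-aware.  Walking stance phases are long
and quiet, so a threshold of 0.6 deg/s on the gyroscope rate magnitude
works (with a 3-sample minimum run length to suppress chatter).  Jogging
and running stance is too short and violent for the threshold rule; instead
a window of 5 samples to each side of the detected Mid-Stance (11 samples,
50 ms each way at 200 Hz) is declared zero-velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, NumericError
from .imu_core import GRAVITY, IMUSequence

ZV_THRESHOLD_DPS = 0.6      # gyroscope-magnitude rule (walking)
ZV_HALF_WINDOW = 5          # samples each side of Mid-Stance (jog/run)
ZV_MIN_RUN = 3              # minimum run length, gyro-threshold mode

#: σv grid evaluated by sweep_sigma_v: 0.001 ... 0.050 m/s in 0.001 steps.
SIGMA_V_GRID = np.round(np.arange(0.001, 0.050 + 1e-9, 0.001), 3)


@dataclass
class FilterParams:
    """Error-state filter noise parameters.

    sigma_a, sigma_w are the accelerometer (m/s²) and gyroscope (rad/s)
    white-noise levels, both defaulting to 0.01; sigma_v (m/s) is the
    pseudo-measurement noise of the zero-velocity observation and is the
    one knob that depends on how hard the foot strikes — pick it with
    :func:`sweep_sigma_v` when a known endpoint is available.
    """

    sigma_a: float = 0.01
    sigma_w: float = 0.01
    sigma_v: float = 0.01
    gravity_mag: float = GRAVITY

    def __post_init__(self) -> None:
        if min(self.sigma_a, self.sigma_w, self.sigma_v) <= 0:
            raise ValueError("all filter sigmas must be > 0")


@dataclass
class NavState:
    """Attitude (body→nav rotation), velocity and position at one instant."""

    C: np.ndarray = field(default_factory=lambda: np.eye(3))
    v: np.ndarray = field(default_factory=lambda: np.zeros(3))
    p: np.ndarray = field(default_factory=lambda: np.zeros(3))
    t: float = 0.0

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float).reshape(3, 3)
        self.v = np.asarray(self.v, dtype=float).reshape(3)
        self.p = np.asarray(self.p, dtype=float).reshape(3)
        if np.linalg.norm(self.C.T @ self.C - np.eye(3)) > 1e-6:
            raise ValueError("attitude matrix is not orthonormal")


@dataclass
class NavHistory:
    """Per-sample strapdown (or filtered) solution."""

    t: np.ndarray                # (N,)
    C: np.ndarray                # (N, 3, 3)
    v: np.ndarray                # (N, 3)
    p: np.ndarray                # (N, 3)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def yaw_deg(self) -> np.ndarray:
        """Heading of the body forward axis, degrees CCW from nav x."""
        return np.degrees(np.arctan2(self.C[:, 1, 0], self.C[:, 0, 0]))


@dataclass
class ZVMask:
    """Boolean zero-velocity mask plus the rule that produced it."""

    mask: np.ndarray
    mode: str                    # "gyro_threshold" | "ms_window"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


# ---------------------------------------------------------------------------
# Zero-velocity detection
# ---------------------------------------------------------------------------

def detect_zero_velocity(
    seq: IMUSequence,
    activity: str,
    ms_indices=None,
    threshold_dps: float = ZV_THRESHOLD_DPS,
    half_window: int = ZV_HALF_WINDOW,
    min_run: int = ZV_MIN_RUN,
) -> ZVMask:
    """Activity-aware zero-velocity mask.

    walking: ``|gyr| < threshold`` (rate magnitude), runs shorter than
    ``min_run`` samples discarded; jog/run: exactly ``[ms - half_window,
    ms + half_window]`` per stride, clipped at the record bounds.
    """
    n = len(seq)
    if activity == "walk":
        mask = np.linalg.norm(seq.gyr, axis=1) < threshold_dps
        if min_run > 1:
            mask = _drop_short_runs(mask, min_run)
        return ZVMask(mask=mask, mode="gyro_threshold")
    if ms_indices is None or len(ms_indices) == 0:
        raise DataError(f"activity '{activity}' needs Mid-Stance indices "
                        "for zero-velocity detection")
    mask = np.zeros(n, dtype=bool)
    for ms in np.asarray(ms_indices, dtype=int):
        mask[max(0, ms - half_window):min(n, ms + half_window + 1)] = True
    return ZVMask(mask=mask, mode="ms_window")


def _drop_short_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    out = mask.copy()
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s < min_run:
            out[s:e] = False
    return out


# ---------------------------------------------------------------------------
# Strapdown propagation
# ---------------------------------------------------------------------------

def _rodrigues(w: np.ndarray) -> np.ndarray:
    """Exact rotation matrix exp([w]×) for a rotation vector w (rad)."""
    angle = np.sqrt(w[0] ** 2 + w[1] ** 2 + w[2] ** 2)
    K = np.array([[0.0, -w[2], w[1]],
                  [w[2], 0.0, -w[0]],
                  [-w[1], w[0], 0.0]])
    if angle < 1e-12:
        return np.eye(3) + K
    A = np.sin(angle) / angle
    B = (1.0 - np.cos(angle)) / angle ** 2
    return np.eye(3) + A * K + B * (K @ K)


def _reorthonormalize(C: np.ndarray) -> np.ndarray:
    """Project back onto SO(3) (symmetric orthogonalisation)."""
    U, _, Vt = np.linalg.svd(C)
    return U @ Vt


def initial_state_from_accelerometer(
    seq: IMUSequence, static_interval: tuple[int, int] | None = None
) -> NavState:
    """Gravity-levelled initial attitude, yaw set to zero.

    Roll/pitch come from the mean accelerometer over the static interval:
    the rotation chosen is the minimal rotation taking the measured specific
    force direction to nav +z.  Absolute heading is unobservable without a
    magnetometer, so trajectories are reconstructed up to a yaw rotation.
    """
    s, e = static_interval if static_interval is not None else (0, min(len(seq), 400))
    f = seq.acc[s:e].mean(axis=0)
    f = f / np.linalg.norm(f)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(f, z)
    sin_a = np.linalg.norm(axis)
    cos_a = float(np.dot(f, z))
    if sin_a < 1e-12:
        R = np.eye(3) if cos_a > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        R = _rodrigues(axis / sin_a * np.arctan2(sin_a, cos_a))
    # R maps body-measured f onto nav z: body→nav attitude with zero yaw.
    return NavState(C=R, v=np.zeros(3), p=np.zeros(3), t=float(seq.t[s]))


def strapdown_integrate(
    seq: IMUSequence,
    initial: NavState | None = None,
    gravity_mag: float = GRAVITY,
) -> NavHistory:
    """Pure first-order strapdown integration (no corrections).

    Per step: ``a_nav = C·f − g``, ``p += v·dt`` (pre-update velocity),
    ``v += a_nav·dt``, ``C ← C·exp([ω·dt]×)``, attitude re-orthonormalised
    periodically.
    """
    if not (np.all(np.isfinite(seq.acc)) and np.all(np.isfinite(seq.gyr))):
        raise NumericError("non-finite IMU samples")
    if initial is None:
        initial = initial_state_from_accelerometer(seq)
    n = len(seq)
    dt = 1.0 / seq.rate_hz
    g_vec = np.array([0.0, 0.0, gravity_mag])
    gyr_rad = np.deg2rad(seq.gyr)

    C_hist = np.empty((n, 3, 3))
    v_hist = np.empty((n, 3))
    p_hist = np.empty((n, 3))
    C = initial.C.copy()
    v = initial.v.copy()
    p = initial.p.copy()
    for k in range(n):
        C_hist[k] = C
        v_hist[k] = v
        p_hist[k] = p
        a_nav = C @ seq.acc[k] - g_vec
        p = p + v * dt
        v = v + a_nav * dt
        C = C @ _rodrigues(gyr_rad[k] * dt)
        if k % 100 == 99:
            C = _reorthonormalize(C)
    return NavHistory(t=seq.t.copy(), C=C_hist, v=v_hist, p=p_hist,
                      meta={"method": "strapdown"})


# ---------------------------------------------------------------------------
# Error-state complementary Kalman filter
# ---------------------------------------------------------------------------

def zupt_kalman(
    seq: IMUSequence,
    zv: ZVMask | np.ndarray,
    params: FilterParams | None = None,
    initial: NavState | None = None,
) -> NavHistory:
    """ZUPT-corrected strapdown via a 9-state error-state Kalman filter.

    Error state x = (φ, δv, δp) in the navigation frame.  Discrete
    propagation: φ constant, δv ← δv − [f_nav]× φ dt, δp ← δp + δv dt, with
    process noise diag(σw², σa², 0)·dt² entering attitude and velocity.  At
    every zero-velocity sample the strapdown velocity is measured as pure
    velocity error (H = [0 I 0], R = σv² I); the posterior error is fed back
    (states corrected, error reset to zero).  With an all-false mask the
    output equals :func:`strapdown_integrate` exactly.
    """
    params = params or FilterParams()
    mask = zv.mask if isinstance(zv, ZVMask) else np.asarray(zv, dtype=bool)
    if len(mask) != len(seq):
        raise DataError("zero-velocity mask length mismatch")
    if not (np.all(np.isfinite(seq.acc)) and np.all(np.isfinite(seq.gyr))):
        raise NumericError("non-finite IMU samples")
    if initial is None:
        initial = initial_state_from_accelerometer(seq)

    n = len(seq)
    dt = 1.0 / seq.rate_hz
    g_vec = np.array([0.0, 0.0, params.gravity_mag])
    gyr_rad = np.deg2rad(seq.gyr)

    C_hist = np.empty((n, 3, 3))
    v_hist = np.empty((n, 3))
    p_hist = np.empty((n, 3))
    C = initial.C.copy()
    v = initial.v.copy()
    p = initial.p.copy()

    P = np.eye(9) * 1e-10
    Q = np.zeros((9, 9))
    Q[0:3, 0:3] = np.eye(3) * (params.sigma_w * dt) ** 2
    Q[3:6, 3:6] = np.eye(3) * (params.sigma_a * dt) ** 2
    R = np.eye(3) * params.sigma_v ** 2
    F = np.eye(9)
    F[6:9, 3:6] = np.eye(3) * dt
    I9 = np.eye(9)
    H = np.zeros((3, 9))
    H[:, 3:6] = np.eye(3)
    n_updates = 0

    for k in range(n):
        # measurement update at sample k, against the covariance propagated
        # up to sample k
        if mask[k]:
            S = P[3:6, 3:6] + R
            K = P[:, 3:6] @ np.linalg.inv(S)
            dx = K @ v                      # measurement z = v̂ − 0
            P = (I9 - K @ H) @ P
            P = 0.5 * (P + P.T)
            if np.any(np.diag(P) < -1e-9):
                raise NumericError(
                    f"error covariance lost positive semidefiniteness at "
                    f"sample {k}: min diag {np.min(np.diag(P)):.3e}"
                )
            # feedback: remove the estimated errors, reset the error state
            C = _rodrigues(-dx[0:3]) @ C
            v = v - dx[3:6]
            p = p - dx[6:9]
            n_updates += 1

        C_hist[k] = C
        v_hist[k] = v
        p_hist[k] = p
        if k == n - 1:
            break

        f_nav = C @ seq.acc[k]
        a_nav = f_nav - g_vec

        # error covariance propagation (attitude→velocity coupling via the
        # skew of the navigation-frame specific force)
        F[3, 1] = f_nav[2] * dt
        F[3, 2] = -f_nav[1] * dt
        F[4, 0] = -f_nav[2] * dt
        F[4, 2] = f_nav[0] * dt
        F[5, 0] = f_nav[1] * dt
        F[5, 1] = -f_nav[0] * dt
        P = F @ P @ F.T + Q

        # strapdown propagation
        p = p + v * dt
        v = v + a_nav * dt
        C = C @ _rodrigues(gyr_rad[k] * dt)
        if k % 100 == 99:
            C = _reorthonormalize(C)

    return NavHistory(
        t=seq.t.copy(), C=C_hist, v=v_hist, p=p_hist,
        meta={"method": "zupt_kalman", "n_updates": n_updates,
              "sigma_v": params.sigma_v},
    )


def sweep_sigma_v(
    seq: IMUSequence,
    zv: ZVMask | np.ndarray,
    params: FilterParams | None = None,
    end_truth=(0.0, 0.0),
    grid=None,
    initial: NavState | None = None,
):
    """Pick the ZUPT measurement noise that minimises the endpoint error.

    Runs the filter for every σv on the grid (default 0.001…0.050 m/s in
    0.001 steps), scores each by the planar distance between the final
    position and ``end_truth``, and returns ``(best_sigma_v, table)`` where
    the table holds (sigma_v, rpe_m).  Ties go to the smaller σv.
    """
    import pandas as pd

    params = params or FilterParams()
    grid = SIGMA_V_GRID if grid is None else np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("sigma_v grid is empty")
    end_truth = np.asarray(end_truth, dtype=float)[:2]
    rows = []
    for sv in grid:
        pp = FilterParams(sigma_a=params.sigma_a, sigma_w=params.sigma_w,
                          sigma_v=float(sv), gravity_mag=params.gravity_mag)
        hist = zupt_kalman(seq, zv, pp, initial=initial)
        rpe = float(np.linalg.norm(hist.p[-1, :2] - end_truth))
        rows.append({"sigma_v": float(sv), "rpe_m": rpe})
    table = pd.DataFrame(rows)
    best = float(table.loc[table["rpe_m"].idxmin(), "sigma_v"])
    return best, table
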