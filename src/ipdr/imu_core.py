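"""Data model, units, calibration, resampling and file I/O for 6-axis IMU records.

The universal input of the pipeline is an :class:`IMUSequence`: a uniformly
sampled tri-axial accelerometer + tri-axial gyroscope record.  Units are fixed
by contract — accelerometer in m/s², gyroscope in deg/s — and any conversion
happens at load time, never downstream.  Every gait threshold used later in
the pipeline (e.g. the 0.6 deg/s zero-velocity threshold) is stated in deg/s,
which is why deg/s is the canonical gyroscope unit; conversion to rad/s is
confined to the strapdown module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError, DataError, FormatError

log = logging.getLogger(__name__)

#: Standard gravity used for g → m/s² conversion.
GRAVITY = 9.81

#: Canonical CSV column order written by :func:`save_imu`.
CANONICAL_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")

#: Longest NaN run (seconds) that may be repaired by linear interpolation.
MAX_NAN_GAP_S = 0.1


@dataclass
class IMUSequence:
    """Uniformly sampled 6-axis inertial record.

    Attributes
    ----------
    t : (N,) float array, seconds on a uniform grid
    acc : (N, 3) float array, m/s²
    gyr : (N, 3) float array, deg/s
    rate_hz : sampling rate, samples/second
    meta : free-form provenance (sensor id, activity label if known)
    """

    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    rate_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyr = np.atleast_2d(np.asarray(self.gyr, dtype=float))
        n = len(self.t)
        if n < 2:
            raise DataError("an IMUSequence needs at least 2 samples")
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise DataError(
                f"acc/gyr must be (N, 3) with N == len(t) == {n}; "
                f"got acc {self.acc.shape}, gyr {self.gyr.shape}"
            )
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise DataError("time vector must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.rate_hz)) > 1e-9:
            raise DataError(
                "time grid is not uniform at the declared rate; "
                "resample before constructing an IMUSequence"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def slice(self, start: int, end: int) -> "IMUSequence":
        """Half-open sample slice [start, end) keeping the time origin."""
        return IMUSequence(
            t=self.t[start:end],
            acc=self.acc[start:end],
            gyr=self.gyr[start:end],
            rate_hz=self.rate_hz,
            meta=dict(self.meta),
        )


@dataclass
class CalibrationInfo:
    """Result of static-interval calibration.

    gyro_bias is the per-axis mean of the gyroscope over a standing-still
    interval; gravity_mag is the mean accelerometer norm over the same
    interval and is later used as the local gravity in strapdown integration.
    """

    gyro_bias: np.ndarray          # (3,) deg/s
    gravity_mag: float             # m/s²
    static_interval: tuple[int, int]

    def __post_init__(self) -> None:
        self.gyro_bias = np.asarray(self.gyro_bias, dtype=float).reshape(3)
        if not (9.0 <= self.gravity_mag <= 10.5):
            raise CalibrationError(
                f"gravity magnitude {self.gravity_mag:.3f} m/s² outside "
                "[9.0, 10.5]; calibration rejected"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_UNIT_FACTORS_ACC = {"m/s2": 1.0, "m/s^2": 1.0, "g": GRAVITY}
_UNIT_FACTORS_GYR = {"deg/s": 1.0, "dps": 1.0, "rad/s": 180.0 / np.pi}


def _interpolate_nans(values: np.ndarray, rate_hz: float, name: str) -> np.ndarray:
    """Repair short NaN runs by linear interpolation from the neighbours.

    Runs longer than MAX_NAN_GAP_S (or NaNs touching either end) are a data
    error: there is nothing defensible to integrate through.
    """
    out = values.copy()
    max_run = max(1, int(round(MAX_NAN_GAP_S * rate_hz)))
    for col in range(out.shape[1]):
        bad = ~np.isfinite(out[:, col])
        if not bad.any():
            continue
        if bad[0] or bad[-1]:
            raise DataError(f"{name} column {col}: NaN at sequence boundary")
        # length of each NaN run
        idx = np.flatnonzero(bad)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            if len(run) > max_run:
                raise DataError(
                    f"{name} column {col}: NaN run of {len(run)} samples "
                    f"exceeds {MAX_NAN_GAP_S} s at rate {rate_hz} Hz"
                )
        good = ~bad
        out[bad, col] = np.interp(
            np.flatnonzero(bad), np.flatnonzero(good), out[good, col]
        )
        log.info("interpolated %d NaN sample(s) in %s column %d",
                 int(bad.sum()), name, col)
    return out


def load_imu(
    path: str | Path,
    column_map: Mapping[str, str | int] | None = None,
    units: Mapping[str, str] | None = None,
    rate_hz: float | None = None,
    delimiter: str | None = None,
    meta: dict | None = None,
) -> IMUSequence:
    """Read a delimited-text IMU recording into canonical units.

    Parameters
    ----------
    column_map
        Maps canonical names (``t, ax, ay, az, gx, gy, gz``) to the file's
        column names (or integer positions).  ``t`` may be omitted when
        ``rate_hz`` is declared.  If a sidecar ``<path>.yaml``/``.json``
        exists it is read for ``column_map``/``units``/``rate_hz`` defaults.
    units
        ``{"acc": "g"|"m/s2", "gyr": "deg/s"|"rad/s", "t": "s"|"ms"}``.
        Defaults to canonical units.
    rate_hz
        Declared rate.  When timestamps are present they are linearly
        resampled onto a uniform grid at this rate; when absent the rate is
        mandatory.  If None, the rate is inferred from the median time delta.
    """
    path = Path(path)
    sidecar = _read_sidecar(path)
    column_map = dict(sidecar.get("column_map", {})) | dict(column_map or {})
    units = dict(sidecar.get("units", {})) | dict(units or {})
    rate_hz = rate_hz if rate_hz is not None else sidecar.get("rate_hz")

    df = pd.read_csv(path, sep=delimiter, engine="python")
    cols = {}
    needed = ["ax", "ay", "az", "gx", "gy", "gz"]
    for name in needed + ["t"]:
        key = column_map.get(name, name)
        if isinstance(key, int):
            if key >= df.shape[1]:
                raise FormatError(f"column index {key} for '{name}' out of range")
            cols[name] = df.iloc[:, key].to_numpy(dtype=float)
        elif key in df.columns:
            cols[name] = df[key].to_numpy(dtype=float)
        elif name == "t":
            cols[name] = None
        else:
            raise FormatError(f"missing column '{key}' for channel '{name}'")

    acc = np.column_stack([cols["ax"], cols["ay"], cols["az"]])
    gyr = np.column_stack([cols["gx"], cols["gy"], cols["gz"]])
    acc = acc * _unit_factor(units.get("acc", "m/s2"), _UNIT_FACTORS_ACC, "acc")
    gyr = gyr * _unit_factor(units.get("gyr", "deg/s"), _UNIT_FACTORS_GYR, "gyr")

    t = cols["t"]
    if t is None:
        if rate_hz is None:
            raise FormatError("no time column and no declared rate")
        t = np.arange(len(acc)) / rate_hz
    else:
        if units.get("t", "s") == "ms":
            t = t / 1000.0
        if np.any(np.diff(t) <= 0):
            raise DataError("time column is not strictly increasing")
        if rate_hz is None:
            rate_hz = 1.0 / float(np.median(np.diff(t)))
            # timestamps printed at finite precision: snap to a round rate
            if abs(rate_hz - round(rate_hz)) < 1e-4 * rate_hz:
                rate_hz = float(round(rate_hz))

    acc = _interpolate_nans(acc, rate_hz, "acc")
    gyr = _interpolate_nans(gyr, rate_hz, "gyr")

    seq_meta = dict(sidecar.get("meta", {})) | dict(meta or {})
    seq_meta.setdefault("source", str(path))
    return _to_uniform_grid(t, acc, gyr, rate_hz, seq_meta)


def _unit_factor(unit: str, table: Mapping[str, float], channel: str) -> float:
    try:
        return table[unit]
    except KeyError:
        raise FormatError(f"unknown {channel} unit '{unit}'") from None


def _read_sidecar(path: Path) -> dict:
    for ext, loader in ((".yaml", yaml.safe_load), (".yml", yaml.safe_load),
                        (".json", json.loads)):
        sc = path.with_suffix(path.suffix + ext)
        if sc.exists():
            return loader(sc.read_text()) or {}
    return {}


def _to_uniform_grid(t, acc, gyr, rate_hz, meta) -> IMUSequence:
    """Linearly resample onto a uniform grid at rate_hz starting at t[0]."""
    n = int(np.floor((t[-1] - t[0]) * rate_hz + 0.5)) + 1
    tu = t[0] + np.arange(n) / rate_hz
    if len(tu) == len(t) and np.max(np.abs(tu - t)) < 1e-9:
        return IMUSequence(t=tu, acc=acc, gyr=gyr, rate_hz=rate_hz, meta=meta)
    acc_u = np.column_stack([np.interp(tu, t, acc[:, i]) for i in range(3)])
    gyr_u = np.column_stack([np.interp(tu, t, gyr[:, i]) for i in range(3)])
    return IMUSequence(t=tu, acc=acc_u, gyr=gyr_u, rate_hz=rate_hz, meta=meta)


def resample(seq: IMUSequence, rate_hz: float) -> IMUSequence:
    """Linear resampling onto a uniform grid at ``rate_hz``.

    Resampling at the native rate is the identity (same arrays re-gridded
    from the same origin).
    """
    if rate_hz == seq.rate_hz:
        return seq
    return _to_uniform_grid(seq.t, seq.acc, seq.gyr, rate_hz, dict(seq.meta))


def save_imu(seq: IMUSequence, path: str | Path, decimals: int = 9) -> None:
    """Write the canonical CSV: header ``t,ax,ay,az,gx,gy,gz``."""
    df = pd.DataFrame(
        np.column_stack([seq.t, seq.acc, seq.gyr]), columns=CANONICAL_COLUMNS
    )
    df.to_csv(path, index=False, float_format=f"%.{decimals}f")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def find_static_prefix(
    seq: IMUSequence, stillness_std_dps: float = 1.0
) -> tuple[int, int]:
    """Longest prefix whose per-axis gyroscope std stays below the ceiling.

    The subject stands still at the start of a recording; we grow the prefix
    in 0.5 s blocks while the running per-axis std remains below
    ``stillness_std_dps``.
    """
    block = max(2, int(round(0.5 * seq.rate_hz)))
    end = block
    n = len(seq)
    while end + block <= n:
        std = seq.gyr[: end + block].std(axis=0)
        if np.any(std >= stillness_std_dps):
            break
        end += block
    return (0, end)


def estimate_gyro_bias(
    seq: IMUSequence,
    static_interval: tuple[int, int] | None = None,
    minimum_static_seconds: float = 2.0,
    stillness_std_dps: float = 1.0,
) -> CalibrationInfo:
    """Constant gyroscope bias and gravity magnitude from a standing interval.

    The bias is the per-axis mean of the gyroscope while the subject stands
    still; gravity is the mean accelerometer norm over the same interval.
    """
    if static_interval is None:
        static_interval = find_static_prefix(seq, stillness_std_dps)
    start, end = static_interval
    n_min = int(np.ceil(minimum_static_seconds * seq.rate_hz))
    if end - start < n_min:
        raise CalibrationError(
            f"static interval [{start}, {end}) has {end - start} samples, "
            f"needs >= {n_min} ({minimum_static_seconds} s at {seq.rate_hz} Hz)"
        )
    g = seq.gyr[start:end]
    std = g.std(axis=0)
    if np.any(std >= stillness_std_dps):
        raise CalibrationError(
            f"gyroscope std {std} deg/s exceeds stillness ceiling "
            f"{stillness_std_dps} deg/s; interval is not static"
        )
    bias = g.mean(axis=0)
    gravity = float(np.linalg.norm(seq.acc[start:end], axis=1).mean())
    return CalibrationInfo(gyro_bias=bias, gravity_mag=gravity,
                           static_interval=(start, end))


def apply_calibration(seq: IMUSequence, cal: CalibrationInfo) -> IMUSequence:
    """Subtract the constant gyroscope bias from the entire sequence."""
    return replace(
        seq,
        gyr=seq.gyr - cal.gyro_bias,
        meta=dict(seq.meta) | {"gyro_bias_removed_dps": cal.gyro_bias.tolist()},
    )
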