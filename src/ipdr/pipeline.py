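"""End-to-end trajectory reconstruction pipeline.

Orchestrates: calibrate → classify activity → select template → msDTW
stride segmentation → TO/MS event detection → activity-aware zero-velocity
detection → ZUPT error-state Kalman filter → stride trajectory → metrics.
When the bout is jogging or running the zero-velocity mode is the
Mid-Stance window; for walking it is the gyroscope-magnitude threshold.

Every stage failure aborts with the stage name.  For a fixed config and
seed the pipeline is deterministic and the report JSON is byte-identical
across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import ActivityClassifier, extract_features, train_synthetic_classifier
from .errors import IPDRError, PipelineError
from .gait_events import StrideSegment, annotate_events, restitch_to_to
from .imu_core import IMUSequence, apply_calibration, estimate_gyro_bias, load_imu
from .msdtw import DEFAULT_THRESHOLD, subsequence_dtw
from .strapdown import (FilterParams, NavHistory, detect_zero_velocity,
                        initial_state_from_accelerometer, sweep_sigma_v,
                        zupt_kalman)
from .templates import StrideTemplate, default_template
from .trajectory import (Trajectory, load_zones, return_position_error,
                         score_events, strides_out_of_trajectory,
                         trajectory_from_states)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; CLI flags override file values."""

    input_path: str | None = None
    output_dir: str = "ipdr_out"
    column_map: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)
    rate_hz: float | None = None

    activity_override: str | None = None
    classifier_path: str | None = None
    template_paths: dict = field(default_factory=dict)   # activity -> file

    msdtw_threshold: float = DEFAULT_THRESHOLD
    tolerance_frac: float = 0.15

    sigma_a: float = 0.01
    sigma_w: float = 0.01
    sigma_v: float = 0.01
    sigma_v_mode: str = "fixed"          # "fixed" | "sweep"
    end_truth: tuple[float, float] = (0.0, 0.0)

    zones_path: str | None = None
    ground_truth_path: str | None = None
    seed: int = 0
    keep_intermediates: bool = False

    def __post_init__(self) -> None:
        if self.activity_override not in (None, "walk", "jog", "run"):
            raise PipelineError(
                f"activity_override '{self.activity_override}' not in "
                "{walk, jog, run}")
        if self.sigma_v_mode not in ("fixed", "sweep"):
            raise PipelineError("sigma_v_mode must be 'fixed' or 'sweep'")
        if not (0 < self.tolerance_frac < 1):
            raise PipelineError("tolerance_frac must be in (0, 1)")
        if self.msdtw_threshold < 0:
            raise PipelineError("msdtw_threshold must be >= 0")
        for s in ("sigma_a", "sigma_w", "sigma_v"):
            if getattr(self, s) <= 0:
                raise PipelineError(f"{s} must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) \
            else json.loads(text)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    report: dict
    trajectory: Trajectory | None
    strides: list[StrideSegment]
    history: NavHistory
    activity: str


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except IPDRError as exc:
                raise PipelineError(f"stage '{name}': {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig, seq: IMUSequence | None = None) -> PipelineResult:
    """Execute the full reconstruction pipeline and write the artifact bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if seq is None:
        if config.input_path is None:
            raise PipelineError("stage 'load': no input path and no sequence")
        seq = _stage("load")(load_imu)(config.input_path,
                                       column_map=config.column_map,
                                       units=config.units,
                                       rate_hz=config.rate_hz)

    # -- calibration --------------------------------------------------------
    cal = _stage("calibrate")(estimate_gyro_bias)(seq)
    seq = apply_calibration(seq, cal)
    log.info("calibration: bias %s dps, gravity %.4f m/s²",
             np.round(cal.gyro_bias, 4), cal.gravity_mag)

    # -- activity classification -------------------------------------------
    if config.activity_override:
        activity = config.activity_override
    else:
        activity = _stage("classify")(_classify)(seq, config)
    log.info("activity: %s", activity)

    # -- template selection -------------------------------------------------
    if activity in config.template_paths:
        template = StrideTemplate.from_json(config.template_paths[activity])
    else:
        template = default_template(activity, rate_hz=seq.rate_hz)

    # -- stride segmentation -------------------------------------------------
    segres = _stage("segment")(subsequence_dtw)(
        seq.gyr[:, 2], template, threshold=config.msdtw_threshold)
    log.info("msDTW: %d segments at threshold %.1f",
             len(segres), config.msdtw_threshold)

    # -- gait events ---------------------------------------------------------
    strides = _stage("events")(restitch_to_to)(
        segres, seq.gyr[:, 2], rate_hz=seq.rate_hz, activity=activity)
    strides = _stage("events")(annotate_events)(strides, seq.gyr[:, 2])
    log.info("events: %d strides after restitch", len(strides))
    ms_indices = [s.ms_idx for s in strides]

    # -- zero-velocity detection --------------------------------------------
    zv = _stage("zero_velocity")(detect_zero_velocity)(
        seq, activity, ms_indices=ms_indices)

    # -- ZUPT Kalman filter --------------------------------------------------
    params = FilterParams(sigma_a=config.sigma_a, sigma_w=config.sigma_w,
                          sigma_v=config.sigma_v,
                          gravity_mag=cal.gravity_mag)
    initial = initial_state_from_accelerometer(seq, cal.static_interval)
    sweep_table = None
    if config.sigma_v_mode == "sweep":
        best, sweep_table = _stage("sigma_v_sweep")(sweep_sigma_v)(
            seq, zv, params, end_truth=config.end_truth, initial=initial)
        params = FilterParams(sigma_a=params.sigma_a, sigma_w=params.sigma_w,
                              sigma_v=best, gravity_mag=params.gravity_mag)
    history = _stage("reconstruct")(zupt_kalman)(seq, zv, params,
                                                 initial=initial)

    # -- trajectory & metrics ------------------------------------------------
    traj = None
    report: dict = {
        "activity": activity,
        "n_strides": len(strides),
        "n_segments": len(segres),
        "zv_mode": zv.mode,
        "sigma_v": params.sigma_v,
        "gyro_bias_dps": [round(float(b), 6) for b in cal.gyro_bias],
        "gravity_mag": round(cal.gravity_mag, 6),
    }
    if strides:
        traj = _stage("trajectory")(trajectory_from_states)(
            history.p, ms_indices)
        rpe_m, rpe_pct = return_position_error(traj, config.end_truth)
        report.update({
            "total_distance_m": round(traj.total_distance, 6),
            "mean_stride_length_m": round(float(traj.stride_lengths.mean()), 6),
            "rpe_m": round(rpe_m, 6),
            "rpe_pct": round(rpe_pct, 6) if rpe_pct is not None else None,
        })
        if config.zones_path:
            zones = load_zones(config.zones_path)
            sot, sot_pct = _stage("sot")(strides_out_of_trajectory)(traj, zones)
            report.update({"sot_count": sot, "sot_pct": round(sot_pct, 6)})

    if config.ground_truth_path:
        report["events"] = _stage("evaluate")(_score_against_truth)(
            strides, config.ground_truth_path, config.tolerance_frac)

    _write_bundle(out, config, report, strides, traj, history, sweep_table)
    return PipelineResult(report=report, trajectory=traj, strides=strides,
                          history=history, activity=activity)


def _classify(seq: IMUSequence, config: PipelineConfig) -> str:
    if config.classifier_path:
        model = ActivityClassifier.load(config.classifier_path)
    else:
        model = train_synthetic_classifier(seed=config.seed)
    return model.classify_bout(extract_features(seq))


def _score_against_truth(strides, gt_path, tolerance_frac) -> dict:
    gt = json.loads(Path(gt_path).read_text())
    bounds = [tuple(b) for b in gt["stride_bounds"]]
    out = {}
    for name, detected, truth in (
        ("to", [s.to_idx for s in strides], gt["to_indices"]),
        ("ms", [s.ms_idx for s in strides], gt["ms_indices"]),
    ):
        rep = score_events(detected, truth, bounds, tolerance_frac)
        out[name] = rep.as_dict()
    return out


def _write_bundle(out, config, report, strides, traj, history, sweep_table):
    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1) + "\n")
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    if strides:
        pd.DataFrame(
            [{"start": s.start, "end": s.end, "to_idx": s.to_idx,
              "hs_idx": s.hs_idx, "ms_idx": s.ms_idx} for s in strides]
        ).to_csv(out / "events.csv", index=False)
    if traj is not None:
        pd.DataFrame({
            "stride_idx": np.arange(traj.n_strides),
            "x": traj.stride_positions[:, 0],
            "y": traj.stride_positions[:, 1],
            "sl": traj.stride_lengths,
            "heading_deg": traj.headings_deg,
        }).to_csv(out / "trajectory.csv", index=False,
                  float_format="%.9f")
    if config.keep_intermediates:
        pd.DataFrame({
            "t": history.t,
            "px": history.p[:, 0], "py": history.p[:, 1], "pz": history.p[:, 2],
            "vx": history.v[:, 0], "vy": history.v[:, 1], "vz": history.v[:, 2],
            "yaw_deg": history.yaw_deg,
        }).to_csv(out / "state.csv", index=False, float_format="%.9f")
        if sweep_table is not None:
            sweep_table.to_csv(out / "sigma_v_sweep.csv", index=False)
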