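import numpy as np
import pytest

from ipdr import (GaitPlan, NoiseModel, apply_calibration, estimate_gyro_bias,
                  plan_trajectory, synthesize_imu)


@pytest.fixture(scope="session")
def walk_gt():
    """Noise-free straight walking bout, 10 strides of 1.0 m / 1.0 s."""
    plan = GaitPlan(activity="walk", n_strides=10, stride_length_m=1.0,
                    stride_time_s=1.0, lead_in_s=2.0, lead_out_s=1.0)
    return plan_trajectory(plan)


@pytest.fixture(scope="session")
def walk_seq_clean(walk_gt):
    return synthesize_imu(walk_gt, NoiseModel.zero())


@pytest.fixture(scope="session")
def walk_loop_noisy():
    """Closed square walking loop with study-condition noise, calibrated."""
    plan = GaitPlan.square_loop("walk", 6)
    gt = plan_trajectory(plan)
    raw = synthesize_imu(gt, NoiseModel(seed=11))
    cal = estimate_gyro_bias(raw)
    return gt, apply_calibration(raw, cal), cal


def per_stride_event_windows(gt, n_signal):
    """TO-to-TO evaluation windows, the terminal one one-median-span long."""
    tos = gt.to_indices
    last = min(n_signal, int(tos[-1] + np.median(np.diff(tos))))
    return list(zip(tos, np.append(tos[1:], last)))
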