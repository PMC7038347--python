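import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import per_stride_event_windows
from ipdr import (GaitPlan, NoiseModel, plan_trajectory, synthesize_imu)
from ipdr.errors import EventError
from ipdr.gait_events import (annotate_events, detect_mid_stance,
                              detect_toe_off, restitch_to_to)


class TestToeOff:
    def test_hand_traceable_example(self):
        stride = [-1, -0.5, 0.2, 1.0, 3.0, 1.0, -1]
        assert detect_toe_off(stride) == 2

    def test_anchored_to_global_maximum_not_early_blip(self):
        """An early positive blip must not capture the Toe-Off."""
        stride = np.concatenate([
            [-2, -1], [0.5, 0.8, 0.5], [-1, -2, -1],     # spurious blip
            [0.3, 2.0, 8.0, 2.0], [-3, -1],              # true swing peak
        ])
        peak = int(np.argmax(stride))
        to = detect_toe_off(stride)
        assert stride[peak] == 8.0
        assert to == 8                     # crossing just before global max
        assert stride[to - 1] <= 0 < stride[to]

    def test_no_positive_sample_is_event_error(self):
        with pytest.raises(EventError):
            detect_toe_off([-1.0, -2.0, -0.5])

    def test_no_crossing_before_max_flags_low_confidence(self):
        idx, confident = detect_toe_off([3.0, 2.0, 1.0, 0.5],
                                        with_confidence=True)
        assert idx == 0 and not confident

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 1000.0))
    def test_invariant_to_positive_rescaling(self, scale):
        stride = np.array([-1, -0.5, 0.2, 1.0, 3.0, 1.0, -1])
        assert detect_toe_off(stride * scale) == detect_toe_off(stride)


class TestMidStance:
    def _plateau_stride(self):
        """200-sample stride with an exact-zero plateau on [120, 160)."""
        s = np.full(200, 0.5)
        s[:10] = -1.0
        s[10:30] = np.linspace(0, 5, 20)      # swing peak region
        s[30:60] = np.linspace(5, -2, 30)     # descent to HS at 59
        s[59] = -2.5                          # heel-strike minimum
        s[120:160] = 0.0
        s[160:] = -1.0
        return s

    def test_zero_plateau_center_wins(self):
        s = self._plateau_stride()
        ms = detect_mid_stance(s)
        assert 120 <= ms < 160                # inside the zero plateau

    def test_equal_energy_tie_goes_to_earlier_window(self):
        s = np.full(200, 2.0)
        s[:5] = -1.0
        s[5:10] = 10.0                        # max peak early
        s[10] = -3.0                          # heel strike
        s[40:60] = 0.0                        # two equal zero-energy windows
        s[80:100] = 0.0
        ms = detect_mid_stance(s)
        assert 40 <= ms < 60

    def test_too_short_stride_rejected(self):
        with pytest.raises(EventError):
            detect_mid_stance(np.ones(30))

    def test_output_between_heel_strike_and_80_percent(self):
        plan = GaitPlan(activity="jog", n_strides=30, lead_in_s=1.0,
                        lead_out_s=0.5)
        gt = plan_trajectory(plan)
        seq = synthesize_imu(gt, NoiseModel(gyr_bias=(0, 0, 0), seed=3))
        z = seq.gyr[:, 2]
        for a, b in per_stride_event_windows(gt, len(z)):
            ms, hs = detect_mid_stance(z[a:b], with_heel_strike=True)
            assert hs <= ms <= 0.8 * (b - a) + 1

    @pytest.mark.parametrize("activity", ["walk", "jog", "run"])
    def test_mid_stance_inside_zero_velocity_interval(self, activity):
        """Detected MS falls in the true zero-velocity window (noisy)."""
        plan = GaitPlan(activity=activity, n_strides=100, lead_in_s=1.0,
                        lead_out_s=0.5, jitter_frac=0.05, jitter_seed=4)
        gt = plan_trajectory(plan)
        seq = synthesize_imu(gt, NoiseModel(acc_noise_std=0.05,
                                            gyr_noise_std=2.0,
                                            gyr_bias=(0, 0, 0), seed=5))
        z = seq.gyr[:, 2]
        hits = 0
        windows = per_stride_event_windows(gt, len(z))
        for k, (a, b) in enumerate(windows):
            ms = a + detect_mid_stance(z[a:b])
            hits += bool(gt.zv_mask[ms])
        assert hits / len(windows) >= 0.99


class TestRestitch:
    def _toy_signal(self, to_positions, n):
        """Signal with a swing-like pulse whose zero-crossing is at each TO."""
        sig = np.full(n, -0.1)
        for to in to_positions:
            sig[to - 3:to] = -1.0
            sig[to:to + 10] = 5.0
        return sig

    def test_adjacent_tos_tile_without_holes(self):
        sig = self._toy_signal([100, 300], 500)
        strides = restitch_to_to([(90, 180), (290, 380)], sig, rate_hz=200)
        assert [(s.start, s.end) for s in strides] == [(100, 300), (300, 500)]

    def test_long_span_truncated_to_1_5_seconds(self):
        sig = self._toy_signal([100, 700], 900)
        strides = restitch_to_to([(90, 180), (690, 780)], sig, rate_hz=200)
        assert (strides[0].start, strides[0].end) == (100, 400)

    def test_truncation_scales_with_rate(self):
        sig = self._toy_signal([100, 700], 900)
        strides = restitch_to_to([(90, 180), (690, 780)], sig, rate_hz=100)
        # 6 s apart at 100 Hz -> keep 1.5 s = 150 samples
        assert (strides[0].start, strides[0].end) == (100, 250)

    def test_empty_segments_give_empty_list(self):
        assert restitch_to_to([], np.zeros(100), rate_hz=200) == []

    def test_segments_without_peak_skipped(self):
        sig = np.full(400, -1.0)
        sig[200:210] = 3.0
        sig[198:200] = -2.0
        strides = restitch_to_to([(20, 80), (190, 260)], sig, rate_hz=200)
        assert len(strides) == 1 and strides[0].to_idx == 200

    def test_pipeline_strides_tile_the_bout(self, walk_gt, walk_seq_clean):
        from ipdr.msdtw import subsequence_dtw
        from ipdr.templates import default_template
        z = walk_seq_clean.gyr[:, 2]
        res = subsequence_dtw(z, default_template("walk"), threshold=25.0)
        strides = annotate_events(
            restitch_to_to(res, z, rate_hz=200), z)
        assert len(strides) == walk_gt.n_strides
        for a, b in zip(strides, strides[1:]):
            assert b.start == a.end        # no holes
        for s in strides:
            assert s.start <= s.to_idx < s.ms_idx < s.end
            assert s.hs_idx < s.ms_idx


class TestEventRecovery:
    @pytest.mark.parametrize("activity", ["walk", "jog", "run"])
    def test_noise_free_recovery_is_perfect(self, activity):
        """TO and MS land within the 15%-of-stride tolerance on every stride."""
        plan = GaitPlan(activity=activity, n_strides=40, lead_in_s=1.0,
                        lead_out_s=0.5, jitter_frac=0.05, jitter_seed=7)
        gt = plan_trajectory(plan)
        seq = synthesize_imu(gt, NoiseModel.zero())
        z = seq.gyr[:, 2]
        for k, (a, b) in enumerate(per_stride_event_windows(gt, len(z))):
            tol = 0.15 * (gt.stride_bounds[k][1] - gt.stride_bounds[k][0])
            to = a + detect_toe_off(z[a:b])
            ms = a + detect_mid_stance(z[a:b])
            assert abs(to - gt.to_indices[k]) <= tol
            assert abs(ms - gt.ms_indices[k]) <= tol
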