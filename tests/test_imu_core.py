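import numpy as np
import pytest

from ipdr import (IMUSequence, apply_calibration, estimate_gyro_bias,
                  load_imu, resample, save_imu)
from ipdr.errors import CalibrationError, DataError, FormatError
from ipdr.imu_core import GRAVITY, find_static_prefix


def _write_csv(path, rows, header="t,ax,ay,az,gx,gy,gz"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


def make_seq(n=400, rate=200.0, acc=None, gyr=None, seed=0):
    rng = np.random.default_rng(seed)
    acc = np.tile([0.0, 0.0, GRAVITY], (n, 1)) if acc is None else acc
    gyr = rng.normal(0, 0.1, (n, 3)) if gyr is None else gyr
    return IMUSequence(t=np.arange(n) / rate, acc=acc, gyr=gyr, rate_hz=rate)


class TestLoad:
    def test_g_units_converted_to_ms2(self, tmp_path):
        p = _write_csv(tmp_path / "a.csv", [
            "0.000,0,0,1.0,0,0,0",
            "0.005,0,0,1.0,0,0,0",
            "0.010,0,0,1.0,0,0,0",
        ])
        seq = load_imu(p, units={"acc": "g"})
        assert np.allclose(seq.acc[:, 2], GRAVITY)

    def test_rate_inferred_from_uniform_timestamps(self, tmp_path):
        p = _write_csv(tmp_path / "a.csv",
                       [f"{i * 0.005:.3f},0,0,9.81,0,0,0" for i in range(3)])
        seq = load_imu(p)
        assert seq.rate_hz == pytest.approx(200.0)

    def test_single_nan_linearly_interpolated(self, tmp_path):
        # gz: 1, 2, NaN, 4, 5 -> midpoint 3 by hand interpolation
        rows = [f"{i * 0.005:.3f},0,0,9.81,0,0,{g}"
                for i, g in enumerate(["1", "2", "nan", "4", "5"])]
        seq = load_imu(_write_csv(tmp_path / "a.csv", rows))
        assert seq.gyr[2, 2] == pytest.approx(3.0)

    def test_long_nan_run_rejected(self, tmp_path):
        gz = ["1"] * 5 + ["nan"] * 25 + ["1"] * 5   # 25 samples = 0.125 s
        rows = [f"{i * 0.005:.3f},0,0,9.81,0,0,{g}" for i, g in enumerate(gz)]
        with pytest.raises(DataError, match="NaN run"):
            load_imu(_write_csv(tmp_path / "a.csv", rows))

    def test_missing_column_is_format_error(self, tmp_path):
        p = (tmp_path / "a.csv")
        p.write_text("t,ax,ay,az\n0,0,0,9.81\n0.005,0,0,9.81\n")
        with pytest.raises(FormatError):
            load_imu(p)

    def test_nonmonotone_time_is_data_error(self, tmp_path):
        rows = ["0.000,0,0,9.81,0,0,0", "0.010,0,0,9.81,0,0,0",
                "0.005,0,0,9.81,0,0,0"]
        with pytest.raises(DataError):
            load_imu(_write_csv(tmp_path / "a.csv", rows))

    def test_column_map_and_declared_rate(self, tmp_path):
        p = (tmp_path / "a.csv")
        p.write_text("AX,AY,AZ,GX,GY,GZ\n" + "1,2,3,4,5,6\n" * 4)
        seq = load_imu(p, column_map={"ax": "AX", "ay": "AY", "az": "AZ",
                                      "gx": "GX", "gy": "GY", "gz": "GZ"},
                       rate_hz=100.0)
        assert len(seq) == 4 and seq.rate_hz == 100.0
        assert np.allclose(seq.gyr[0], [4, 5, 6])


class TestRoundTrip:
    def test_save_load_reproduces_samples(self, tmp_path):
        seq = make_seq(seed=1)
        save_imu(seq, tmp_path / "s.csv")
        back = load_imu(tmp_path / "s.csv")
        assert np.allclose(back.acc, seq.acc, atol=1e-8)
        assert np.allclose(back.gyr, seq.gyr, atol=1e-8)

    def test_resample_at_native_rate_is_identity(self):
        seq = make_seq()
        out = resample(seq, seq.rate_hz)
        assert out is seq

    def test_resample_halves_sample_count(self):
        seq = make_seq(n=401)
        out = resample(seq, 100.0)
        assert out.rate_hz == 100.0
        assert len(out) == 201
        assert np.allclose(out.acc[:, 2], GRAVITY)


class TestCalibration:
    def test_constant_bias_and_gravity_recovered(self):
        gyr = np.tile([0.5, -0.2, 0.1], (2000, 1))
        seq = make_seq(n=2000, gyr=gyr)
        cal = estimate_gyro_bias(seq, static_interval=(0, 2000))
        assert np.allclose(cal.gyro_bias, [0.5, -0.2, 0.1])
        assert cal.gravity_mag == pytest.approx(GRAVITY)

    def test_white_noise_bias_below_sem_bound(self):
        rng = np.random.default_rng(42)
        seq = make_seq(n=2000, gyr=rng.normal(0, 0.05, (2000, 3)))
        cal = estimate_gyro_bias(seq, static_interval=(0, 2000))
        assert np.all(np.abs(cal.gyro_bias) < 0.01)   # ~9 standard errors

    def test_interval_too_short_rejected(self):
        seq = make_seq(n=400)
        with pytest.raises(CalibrationError, match="samples"):
            estimate_gyro_bias(seq, static_interval=(0, 100))

    def test_noisy_interval_rejected(self):
        rng = np.random.default_rng(0)
        seq = make_seq(n=2000, gyr=rng.normal(0, 5.0, (2000, 3)))
        with pytest.raises(CalibrationError, match="stillness"):
            estimate_gyro_bias(seq, static_interval=(0, 2000))

    def test_implausible_gravity_rejected(self):
        seq = make_seq(n=800, acc=np.tile([0.0, 0.0, 5.0], (800, 1)))
        with pytest.raises(CalibrationError, match="gravity"):
            estimate_gyro_bias(seq, static_interval=(0, 800))

    def test_static_prefix_detected_before_motion(self):
        gyr = np.zeros((1000, 3))
        gyr[600:, 2] = 200.0        # swing-like motion after 3 s
        seq = make_seq(n=1000, gyr=gyr)
        start, end = find_static_prefix(seq)
        assert start == 0 and 400 <= end <= 600

    def test_apply_calibration_subtracts_bias(self):
        seq = make_seq(n=2000, gyr=np.tile([0.5, 0.0, 0.0], (2000, 1)))
        cal = estimate_gyro_bias(seq, static_interval=(0, 2000))
        out = apply_calibration(seq, cal)
        assert np.allclose(out.gyr, 0.0)
        # re-estimated bias on the output is ~0: second application inert
        cal2 = estimate_gyro_bias(out, static_interval=(0, 2000))
        assert np.all(np.abs(cal2.gyro_bias) < 1e-12)

    def test_zero_bias_is_identity(self):
        seq = make_seq(seed=3)
        cal = estimate_gyro_bias(seq, static_interval=(0, 400),
                                 minimum_static_seconds=1.0)
        out = apply_calibration(seq, type(cal)(gyro_bias=np.zeros(3),
                                               gravity_mag=cal.gravity_mag,
                                               static_interval=(0, 400)))
        assert np.array_equal(out.gyr, seq.gyr)

    def test_residual_angle_integral_small_after_calibration(self):
        # stationary 10 s with bias + noise: post-calibration angular drift
        rng = np.random.default_rng(7)
        gyr = np.array([0.5, -0.3, 0.2]) + rng.normal(0, 0.05, (2000, 3))
        seq = make_seq(n=2000, gyr=gyr)
        out = apply_calibration(seq, estimate_gyro_bias(seq, (0, 2000)))
        drift_deg = np.abs(np.trapezoid(out.gyr, dx=1 / 200.0, axis=0))
        assert np.all(drift_deg < 0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_injected_bias_recovered_within_3_standard_errors(self, seed):
        rng = np.random.default_rng(seed)
        bias = np.array([0.5, -0.3, 0.2])
        noise_std = 0.2
        n = 2000
        seq = make_seq(n=n, gyr=bias + rng.normal(0, noise_std, (n, 3)))
        cal = estimate_gyro_bias(seq, static_interval=(0, n))
        assert np.all(np.abs(cal.gyro_bias - bias) < 3 * noise_std / np.sqrt(n))
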