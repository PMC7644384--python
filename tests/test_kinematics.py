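import numpy as np
import pytest

import penlaws as pl
from penlaws.errors import TooShortError, ValidationError
from penlaws.kinematics import SpeedProfile
from penlaws.synthetic import MotorProfile, min_jerk_speed

from conftest import make_trial


def line_trial(n, dt=0.02, speed=100.0):
    t = np.arange(n) * dt
    return make_trial(t, speed * t, np.zeros(n))


class TestTrimBorders:
    @pytest.mark.parametrize("n,fraction,kept", [(100, 0.05, 90), (20, 0.05, 18)])
    def test_floor_arithmetic(self, n, fraction, kept):
        out = pl.trim_borders(line_trial(n), fraction)
        assert len(out) == kept
        k = (n - kept) // 2
        np.testing.assert_array_equal(out.t, line_trial(n).t[k:n - k])

    def test_zero_fraction_is_identity(self):
        trial = line_trial(30)
        np.testing.assert_array_equal(pl.trim_borders(trial, 0.0).t, trial.t)

    def test_removes_exactly_two_floor_fraction_n(self):
        for n in (10, 37, 100, 101):
            out = pl.trim_borders(line_trial(n), 0.05)
            assert len(out) == n - 2 * int(np.floor(0.05 * n))

    def test_overtrim_raises(self):
        with pytest.raises(TooShortError):
            pl.trim_borders(line_trial(5), 0.45)


class TestPathLength:
    def test_collinear_samples(self):
        trial = make_trial([0, 0.02, 0.04], [0, 10, 25], [0, 0, 0])
        assert pl.path_length(trial) == pytest.approx(25.0)

    def test_unit_square_perimeter(self):
        xy = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]], float)
        trial = make_trial(np.arange(5) * 0.02, xy[:, 0], xy[:, 1])
        assert pl.path_length(trial) == pytest.approx(40.0)

    def test_pen_up_gap_contributes_zero(self):
        trial = make_trial(np.arange(5) * 0.02, [0, 10, 100, 110, 120], [0] * 5,
                           pen_down=[1, 1, 0, 1, 1])
        # only segments with both endpoints pen-down count: 0->10 and 110->120
        assert pl.path_length(trial) == pytest.approx(20.0)

    def test_generated_circle_matches_perimeter(self, noiseless_profile):
        trial = pl.generate_copy_trial(noiseless_profile, "circle",
                                       "spontaneous", size_mm=120.0, seed=0)
        assert pl.path_length(trial) == pytest.approx(120.0, rel=0.005)


class TestRawSpeed:
    def test_constant_velocity(self):
        prof = pl.raw_speed(line_trial(50, speed=500.0))
        np.testing.assert_allclose(prof.v, 500.0)

    def test_stationary_pen(self):
        t = np.arange(20) * 0.02
        prof = pl.raw_speed(make_trial(t, np.zeros(20), np.zeros(20)))
        np.testing.assert_allclose(prof.v, 0.0)

    def test_duplicate_timestamp_names_index(self):
        trial = make_trial([0.0, 0.02, 0.02, 0.04], np.arange(4), np.zeros(4))
        with pytest.raises(ValidationError, match="index 1"):
            pl.raw_speed(trial)

    def test_minimum_jerk_profile_matches_closed_form(self, noiseless_profile):
        trial = pl.generate_copy_trial(noiseless_profile, "circle",
                                       "spontaneous", size_mm=120.0, seed=0)
        prof = pl.raw_speed(trial)
        T = trial.truth["pen_down_duration"]
        L = trial.truth["arc_length"]
        tau = prof.t_mid / T
        expected = min_jerk_speed(np.clip(tau, 0, 1)) * L / T
        rms = np.sqrt(np.mean((prof.v - expected) ** 2)) / (L / T)
        assert rms < 0.02


class TestLowpass:
    def _profile(self, v, dt=0.02):
        t = np.arange(len(v)) * dt + dt / 2
        return SpeedProfile(t_mid=t, v=np.asarray(v, float))

    def test_dc_gain_is_one(self):
        out = pl.lowpass(self._profile(np.full(100, 250.0)))
        np.testing.assert_allclose(out.v, 250.0, rtol=1e-6)
        assert out.filtered

    def test_20hz_ripple_attenuated(self):
        t = np.arange(500) * 0.02
        v = 300.0 + 50.0 * np.sin(2 * np.pi * 20.0 * (t + 0.01))
        out = pl.lowpass(SpeedProfile(t_mid=t, v=v))
        ripple = out.v[100:-100] - 300.0
        assert np.abs(ripple).max() < 0.1 * 50.0

    def test_1hz_passband_preserved(self):
        t = np.arange(500) * 0.02
        v = 300.0 + 50.0 * np.sin(2 * np.pi * 1.0 * t)
        out = pl.lowpass(SpeedProfile(t_mid=t, v=v))
        amp = (out.v[100:-100].max() - out.v[100:-100].min()) / 2.0
        assert amp == pytest.approx(50.0, rel=0.05)

    def test_too_short_instructs_fallback(self):
        with pytest.raises(TooShortError, match="raw"):
            pl.lowpass(self._profile(np.full(8, 10.0)))


class TestMeanSpeed:
    def test_constant_velocity_recovered(self, constant_velocity_trial):
        assert pl.mean_speed(constant_velocity_trial) == pytest.approx(120.0, rel=0.01)

    def test_time_rescaling_doubles_speed(self, noiseless_profile):
        slow = pl.generate_copy_trial(noiseless_profile, "circle",
                                      "spontaneous", seed=0)
        fast = make_trial(slow.t / 2.0, slow.x, slow.y)
        ratio = pl.mean_speed(fast) / pl.mean_speed(slow)
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_scale_equivariance(self, noiseless_profile):
        trial = pl.generate_copy_trial(noiseless_profile, "circle",
                                       "spontaneous", seed=0)
        scaled = make_trial(trial.t, 3.0 * trial.x, 3.0 * trial.y)
        assert pl.mean_speed(scaled) == pytest.approx(3.0 * pl.mean_speed(trial),
                                                      rel=1e-9)
        assert pl.path_length(scaled) == pytest.approx(3.0 * pl.path_length(trial),
                                                       rel=1e-9)

    def test_isochrony_compliant_big_doubles_speed(self):
        prof = MotorProfile(isochrony_exponent=1.0, lateral_noise_sd=0.0,
                            fraction_noise_sd=0.0)
        spont = pl.generate_copy_trial(prof, "circle", "spontaneous", seed=1)
        big = pl.generate_copy_trial(prof, "circle", "big", seed=2)
        assert pl.mean_speed(big) / pl.mean_speed(spont) == pytest.approx(2.0, rel=0.02)
        # and durations stay equal (isochrony)
        assert big.t[-1] == pytest.approx(spont.t[-1], rel=0.02)
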