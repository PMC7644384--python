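import numpy as np
import pytest

import penlaws as pl
from penlaws.errors import ConfigError, IncompleteTrialError
from penlaws.steering import TunnelGeometry
from penlaws.synthetic import MotorProfile

from conftest import make_trial


def straight_geometry(length=200.0, W=1.0):
    """Open straight tunnel, handy for constructed accuracy fixtures."""
    xy = np.column_stack([np.linspace(0, length, 401), np.zeros(401)])
    return TunnelGeometry(geometry_id="fx", item="word_ele", center_path=xy,
                          W=W, A=length, laps_required=1,
                          gates=(0.1 * length, 0.9 * length))


def outside_trace(geom, fraction):
    """Trace with exactly `fraction` of its arc length offset by W.

    Solves for the on-path/off-path split so that the connecting jump
    (length W) is part of the total arc.
    """
    L, W = geom.A, geom.W
    total = L + W  # on-path + offset + one jump of length W
    b = fraction * total
    a = L - b
    xs = np.concatenate([np.linspace(0, a, 200),
                         np.linspace(a, a + b, 200)])
    ys = np.concatenate([np.zeros(200), np.full(200, W)])
    t = np.arange(len(xs)) * 0.02
    return make_trial(t, xs, ys, game="tunnel", item="word_ele",
                      geometry_id="fx")


class TestMakeGeometry:
    def test_circle_radius_and_id(self):
        geom = pl.make_geometry("circle", A=100 * np.pi, W=10.0)
        assert geom.ID == pytest.approx(10 * np.pi)
        r = np.hypot(*geom.center_path.T)
        assert np.allclose(r, r[0]) and r[0] == pytest.approx(50.0, rel=1e-3)

    def test_square_side_and_id(self):
        geom = pl.make_geometry("square", A=160.0, W=8.0)
        assert geom.ID == pytest.approx(20.0)
        assert geom.center_path[:, 0].max() == pytest.approx(40.0)

    def test_word_arc_length_matches_amplitude(self):
        geom = pl.make_geometry("word_ele", A=200.0, W=10.0)
        seg = np.hypot(*np.diff(geom.center_path, axis=0).T)
        assert seg.sum() == pytest.approx(200.0, rel=1e-3)

    def test_id_homogeneity_under_joint_scaling(self):
        g1 = pl.make_geometry("circle", A=150.0, W=10.0)
        g2 = pl.make_geometry("circle", A=300.0, W=20.0)
        assert g1.ID == g2.ID

    def test_unsupported_item(self):
        with pytest.raises(ConfigError):
            pl.make_geometry("triangle", A=100.0, W=10.0)


class TestOutsideFraction:
    def test_on_center_path_is_zero(self):
        geom = straight_geometry()
        trial = make_trial(np.arange(100) * 0.02, np.linspace(0, 200, 100),
                           np.zeros(100), game="tunnel", item="word_ele",
                           geometry_id="fx")
        assert pl.outside_fraction(trial, geom) == 0.0

    def test_everywhere_offset_by_w_is_one(self):
        geom = straight_geometry()
        trial = make_trial(np.arange(100) * 0.02, np.linspace(0, 200, 100),
                           np.full(100, geom.W), game="tunnel",
                           item="word_ele", geometry_id="fx")
        assert pl.outside_fraction(trial, geom) == 1.0

    @pytest.mark.parametrize("fraction,expect_excluded",
                             [(0.41, True), (0.39, False), (0.40, False)])
    def test_exclusion_rule_strict_boundary(self, fraction, expect_excluded):
        geom = straight_geometry()
        trial = outside_trace(geom, fraction)
        st = pl.evaluate_trial(trial, geom)
        assert st.outside_fraction == pytest.approx(fraction, abs=0.01)
        assert st.excluded is expect_excluded


class TestMovementTime:
    def test_constant_speed_circle_two_laps(self):
        geom = pl.make_geometry("circle", A=150.0, W=10.0)
        P = geom.line.length
        # ideal trace: 2 laps in 8 s -> central lap takes 4 s
        n = 400
        t = np.linspace(0, 8, n + 1)
        s = np.mod(2 * P * t / 8.0, P)
        arc = geom.arc_table if hasattr(geom, "arc_table") else None
        d = np.hypot(*np.diff(geom.center_path, axis=0).T)
        cum = np.concatenate(([0], np.cumsum(d)))
        x = np.interp(s, cum, geom.center_path[:, 0])
        y = np.interp(s, cum, geom.center_path[:, 1])
        trial = make_trial(t, x, y, game="tunnel", item="circle",
                           geometry_id=geom.geometry_id)
        assert pl.movement_time(trial, geom) == pytest.approx(4.0, abs=0.03)

    def test_constant_speed_word_between_gates(self):
        geom = straight_geometry(length=200.0)
        t = np.linspace(0, 5, 251)
        trial = make_trial(t, 200.0 * t / 5.0, np.zeros_like(t), game="tunnel",
                           item="word_ele", geometry_id="fx")
        # gates at 10% and 90% of the path, constant speed: MT = 0.8 * 5 s
        assert pl.movement_time(trial, geom) == pytest.approx(4.0, abs=0.02)

    def test_incomplete_trial_raises(self):
        geom = pl.make_geometry("circle", A=150.0, W=10.0)
        # only a quarter lap traced
        d = np.hypot(*np.diff(geom.center_path, axis=0).T)
        cum = np.concatenate(([0], np.cumsum(d)))
        s = np.linspace(0, 0.25 * geom.line.length, 100)
        trial = make_trial(np.arange(100) * 0.02,
                           np.interp(s, cum, geom.center_path[:, 0]),
                           np.interp(s, cum, geom.center_path[:, 1]),
                           game="tunnel", item="circle",
                           geometry_id=geom.geometry_id)
        with pytest.raises(IncompleteTrialError):
            pl.movement_time(trial, geom)

    @pytest.mark.parametrize("item,ID", [("circle", 18.0), ("square", 12.0),
                                         ("word_ele", 14.0)])
    def test_generated_trial_recovers_programmed_mt(self, item, ID):
        geom = pl.make_geometry(item, A=150.0, W=150.0 / ID)
        prof = MotorProfile(mt_noise_sd=0.0, lateral_noise_sd=0.0)
        trial = pl.generate_tunnel_trial(prof, geom, seed=9)
        mt = pl.movement_time(trial, geom)
        assert mt == pytest.approx(trial.truth["MT"], abs=0.02 + 1e-9)

    def test_mt_robust_to_lateral_jitter(self):
        geom = pl.make_geometry("circle", A=150.0, W=15.0)
        prof_clean = MotorProfile(mt_noise_sd=0.0, lateral_noise_sd=0.0)
        prof_noisy = MotorProfile(mt_noise_sd=0.0, lateral_noise_sd=1.0)
        clean = pl.generate_tunnel_trial(prof_clean, geom, seed=4)
        noisy = pl.generate_tunnel_trial(prof_noisy, geom, seed=4)
        assert pl.movement_time(noisy, geom) == pytest.approx(
            pl.movement_time(clean, geom), abs=0.06)


class TestFitSteering:
    def test_noiseless_fit_is_exact(self):
        ids = np.array([8.0, 12.0, 18.0, 27.0, 40.0])
        pairs = [(i, 0.5 + 0.1 * i) for i in ids]
        fit = pl.fit_steering(pairs)
        assert fit.a == pytest.approx(0.5, abs=1e-9)
        assert fit.b == pytest.approx(0.1, abs=1e-9)
        assert fit.R2 == pytest.approx(1.0, abs=1e-9)
        assert fit.RMSE == pytest.approx(0.0, abs=1e-9)
        assert fit.IP == pytest.approx(10.0, abs=1e-6)
        assert fit.global_MT == pytest.approx(0.5 + 0.1 * np.median(ids))

    def test_constant_mt_not_significant(self):
        pairs = [(i, 2.0) for i in (8.0, 12.0, 18.0, 27.0, 40.0)]
        fit = pl.fit_steering(pairs)
        assert fit.R2 == pytest.approx(0.0, abs=1e-12)
        assert fit.IP is None

    def test_degenerate_single_id(self):
        with pytest.raises(ConfigError):
            pl.fit_steering([(10.0, 1.0), (10.0, 1.2), (10.0, 1.4)])


class TestCriticalR2:
    def test_study_threshold_df12(self):
        assert round(pl.critical_r2(12, 0.05), 2) == 0.28
        assert pl.critical_r2(12, 0.05) == pytest.approx(0.2835, abs=5e-5)

    def test_alpha_to_one_limit(self):
        assert pl.critical_r2(12, 0.999) < 1e-4

    def test_matches_f_quantile_identity(self):
        from scipy.stats import f
        F = f.ppf(0.95, 1, 12)
        assert F == pytest.approx(4.747, abs=5e-4)
        assert pl.critical_r2(12, 0.05) == pytest.approx(F / (F + 12), rel=1e-12)
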