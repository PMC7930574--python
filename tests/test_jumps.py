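"""Loaded-CMJ mechanics and load-velocity profiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from judoperf.errors import FitError, NoConcentricPhaseError, ProfileError
from judoperf.jumps import (
    JumpTrial,
    LinearFit,
    derive_profile,
    fit_load_velocity,
    jump_height_from_flight_time,
    load_at_velocity,
    mean_propulsive_velocity,
    select_best_jump,
)


class TestMeanPropulsiveVelocity:
    def test_linear_ramp_then_hard_brake(self):
        dt = 1e-4
        t = np.arange(0.0, 0.3, dt)
        rise = 10.0 * t
        fall = 3.0 - 20.0 * np.arange(1, 2000) * dt
        v = np.concatenate([rise, [3.0], fall])
        mpv, (start, end) = mean_propulsive_velocity(v, dt)
        # −20 m/s² < −9.81 terminates the propulsive phase at the 0.3 s corner
        assert end * dt == pytest.approx(0.3, abs=2 * dt)
        assert mpv == pytest.approx(1.5, abs=2e-3)

    def test_constant_velocity_keeps_whole_phase(self):
        v = np.full(500, 2.0)
        mpv, (start, end) = mean_propulsive_velocity(v, 0.001)
        assert mpv == pytest.approx(2.0)
        assert (start, end) == (0, 500)

    def test_gentle_deceleration_keeps_full_concentric_phase(self):
        dt = 0.001
        # decelerates at −5 m/s² throughout: never below the −9.81 cutoff
        v = 2.0 - 5.0 * np.arange(300) * dt
        mpv, (start, end) = mean_propulsive_velocity(v, dt)
        assert end == 300
        assert mpv == pytest.approx(v.mean())

    def test_no_positive_velocity_rejected(self):
        with pytest.raises(NoConcentricPhaseError):
            mean_propulsive_velocity(-np.ones(100), 0.001)

    def test_noisy_one_rm_bias_below_5pct(self):
        """4-load protocol with 0.05 m/s velocity noise: mean recovered 1RM
        stays within 5% of the generating line's 1RM (smoothed pipeline)."""
        from judoperf.jumps import fit_load_velocity, load_at_velocity, smooth_velocity
        from judoperf.synthetic import SubjectTruth, simulate_jump_velocity_trace

        subj = SubjectTruth(
            subject_id="S001", group="hypoxia", body_mass=84.5,
            true_pv_intercept=3.0, true_pv_slope=-0.014,
            true_mpv_intercept=1.5, true_mpv_slope=-0.0075,
        )
        true_one_rm = (1.5 - 0.33) / 0.0075
        recovered = []
        for rep in range(150):
            pts = []
            for load in (20.0, 40.0, 60.0, 80.0):
                v, _ = simulate_jump_velocity_trace(subj, load, seed=1000 * rep + int(load),
                                                    noise_sd=0.05)
                mpv, _seg = mean_propulsive_velocity(v, 0.001, smooth_cutoff=20.0)
                pts.append((load, mpv))
            recovered.append(load_at_velocity(fit_load_velocity(pts), 0.33))
        bias = abs(np.mean(recovered) - true_one_rm) / true_one_rm
        assert bias < 0.05, f"1RM bias {100 * bias:.1f}%"


class TestLoadVelocityFit:
    def test_collinear_points_recovered_exactly(self):
        pts = [(20, 2.72), (40, 2.44), (60, 2.16), (80, 1.88)]
        fit = fit_load_velocity(pts)
        assert fit.intercept == pytest.approx(3.0)
        assert fit.slope == pytest.approx(-0.014)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_points == 4

    def test_two_point_line(self):
        fit = fit_load_velocity([(0, 3.0), (100, 2.0)])
        assert fit.slope == pytest.approx(-0.01)
        assert fit.intercept == pytest.approx(3.0)

    def test_single_distinct_load_rejected(self):
        with pytest.raises(FitError):
            fit_load_velocity([(40, 2.4), (40, 2.5), (40, 2.45)])

    def test_positive_slope_flagged(self):
        with pytest.warns(UserWarning):
            fit = fit_load_velocity([(20, 2.0), (40, 2.5)])
        assert fit.positive_slope


class TestDeriveProfile:
    mpv_fit = LinearFit(intercept=1.5, slope=-0.01, r_squared=1.0, n_points=4)
    pv_fit = LinearFit(intercept=3.0, slope=-0.014, r_squared=1.0, n_points=4)

    def test_one_rm_solves_mpv_line_at_033(self):
        prof = derive_profile(self.pv_fit, self.mpv_fit, body_mass=84.5)
        assert prof.one_rm == pytest.approx(117.0)
        assert prof.one_rm_norm == pytest.approx(117.0 / 84.5)

    def test_v0_l0_slope_closed_form(self):
        prof = derive_profile(self.pv_fit, self.mpv_fit, body_mass=84.5)
        assert prof.v0 == pytest.approx(3.0)
        assert prof.l0 == pytest.approx(3.0 / 0.014)
        assert prof.slope_param == pytest.approx(-1.0 / 0.014)
        # consistency identity to machine precision
        assert prof.slope_param * prof.v0 == pytest.approx(-prof.l0, rel=1e-14)

    def test_pv_at_body_mass_fractions(self):
        prof = derive_profile(self.pv_fit, self.mpv_fit, body_mass=84.0)
        assert prof.pv_at_bm[25] == pytest.approx(3.0 - 0.014 * 21.0)
        assert prof.pv_at_bm[100] == pytest.approx(3.0 - 0.014 * 84.0)
        vals = [prof.pv_at_bm[f] for f in (25, 50, 75, 100)]
        assert all(a > b for a, b in zip(vals, vals[1:]))  # strictly decreasing

    def test_mpv_source_option(self):
        prof = derive_profile(self.pv_fit, self.mpv_fit, body_mass=84.0, source_fit="mpv")
        assert prof.v0 == pytest.approx(1.5)
        assert prof.slope_param == pytest.approx(-100.0)


class TestLoadAtVelocity:
    fit = LinearFit(intercept=1.5, slope=-0.01, r_squared=1.0, n_points=3)

    def test_training_load_at_1_2(self):
        assert load_at_velocity(self.fit, 1.2) == pytest.approx(30.0)

    def test_intercept_velocity_gives_zero_load(self):
        assert load_at_velocity(self.fit, 1.5) == pytest.approx(0.0)

    def test_velocity_above_intercept_rejected(self):
        with pytest.raises(ProfileError):
            load_at_velocity(self.fit, 1.6)

    @settings(max_examples=30, deadline=None)
    @given(load=st.floats(min_value=0.0, max_value=140.0))
    def test_inverse_roundtrip(self, load):
        v = self.fit.predict(load)
        assert load_at_velocity(self.fit, v) == pytest.approx(load, abs=1e-9)


class TestJumpHeight:
    @pytest.mark.parametrize(
        "t, expected",
        [(0.0, 0.0), (0.49, 29.444), (0.5535, 37.568)],
    )
    def test_flight_time_formula(self, t, expected):
        assert jump_height_from_flight_time(t) == pytest.approx(expected, abs=5e-3)

    def test_negative_flight_time_rejected(self):
        with pytest.raises(ValueError):
            jump_height_from_flight_time(-0.1)


class TestSelectBestJump:
    def test_max_pv_per_load(self):
        trials = [JumpTrial(load=20, pv=2.5), JumpTrial(load=20, pv=2.6),
                  JumpTrial(load=40, pv=2.2)]
        best = select_best_jump(trials)
        assert best[20].pv == 2.6
        assert best[40].pv == 2.2

    def test_single_trial_is_itself(self):
        tr = JumpTrial(load=20, pv=2.5)
        assert select_best_jump([tr])[20] is tr

    def test_highest_unloaded_jump(self):
        a = JumpTrial(load=0, flight_time=0.533)  # ~34.9 cm
        b = JumpTrial(load=0, flight_time=0.536)  # ~35.2 cm
        assert select_best_jump([a, b], per_load=False) is b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_jump([])
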