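import numpy as np
import pytest
from scipy.integrate import solve_ivp

from beeland.kinematics import StateSeries
from beeland.trajio import FS_HZ
from beeland.transient import (accel_error_correlation, closed_form_y,
                               distance_discrepancy, fit_constant_rdot,
                               mean_acceleration, simulate_constant_rdot)

from conftest import states_from_r


class TestFitConstantRdot:
    def test_exact_linear_signal(self):
        t = np.arange(0, 0.5, 1 / FS_HZ)
        rdot, c, r2 = fit_constant_rdot(10 * t + 0.5, t)
        assert rdot == pytest.approx(10.0, abs=1e-9)
        assert c == pytest.approx(0.5, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_slope_within_three_se(self):
        rng = np.random.default_rng(11)
        t = np.arange(100) / FS_HZ
        sigma = 0.05
        r = 8.0 * t + 1.0 + rng.normal(0, sigma, 100)
        rdot, _, _ = fit_constant_rdot(r, t)
        sxx = np.sum((t - t.mean()) ** 2)
        se = sigma / np.sqrt(sxx)
        assert abs(rdot - 8.0) < 3 * se

    def test_constant_signal_r2_zero(self):
        t = np.arange(20) / FS_HZ
        rdot, c, r2 = fit_constant_rdot(np.full(20, 1.5), t)
        assert rdot == pytest.approx(0.0, abs=1e-9)
        assert r2 == 0.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_constant_rdot(np.array([1.0, 2.0]), np.array([0.0, 0.1]))


class TestConstantRdotMotion:
    def test_zero_rdot_reduces_to_exponential(self):
        st = simulate_constant_rdot(0.3, 2.0, 0.0, 0.5)
        np.testing.assert_allclose(st.y, 0.3 * np.exp(-2.0 * st.t), rtol=1e-12)
        np.testing.assert_allclose(st.r, 2.0, atol=1e-12)

    def test_closed_form_value(self):
        y = closed_form_y(0.3, 1.0, 10.0, np.array([0.2]))[0]
        assert y == pytest.approx(0.3 * np.exp(-(0.2 + 10 * 0.2**2 / 2)), rel=1e-12)
        assert y == pytest.approx(0.201, abs=5e-4)

    @pytest.mark.parametrize("y0", [0.1, 0.2, 0.3])
    @pytest.mark.parametrize("r0", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("rdot", [-5.0, 0.0, 5.0, 20.0])
    def test_closed_form_matches_ode(self, y0, r0, rdot):
        t = np.linspace(0, 1.0, 176)
        sol = solve_ivp(lambda tt, s: [-(r0 + rdot * tt) * s[0]], (0, 1), [y0],
                        t_eval=t, rtol=1e-11, atol=1e-13)
        assert np.max(np.abs(closed_form_y(y0, r0, rdot, t) - sol.y[0])) < 1e-8

    def test_initial_velocity_from_setpoint_step(self):
        # V(t0) = (r* - dre) * y0: a step of 2 toward r* = 3 from y0 = 0.25
        r_star, dre, y0 = 3.0, 2.0, 0.25
        st = simulate_constant_rdot(y0, r_star - dre, 10.0, 0.2)
        assert st.V[0] == pytest.approx((r_star - dre) * y0, rel=1e-12)

    def test_truncates_at_floor(self):
        st = simulate_constant_rdot(0.05, 3.0, 20.0, 5.0)
        assert st.y.min() >= 0.005
        assert st.t[-1] < 5.0


class TestDistanceDiscrepancy:
    def test_exact_constant_rdot_entry_has_zero_delta_d(self):
        st = simulate_constant_rdot(0.25, 1.0, 8.0, 0.25)
        rdot, c, _ = fit_constant_rdot(st.r, st.t)
        assert abs(distance_discrepancy(st, rdot, c)) < 1e-9

    def test_oscillation_bounds_delta_d(self):
        t = np.arange(0, 0.3, 1 / FS_HZ)
        r = 1.0 + 8.0 * t
        st = states_from_r(r, t, y0=0.25)
        st.y += 0.002 * np.sin(2 * np.pi * 10 * t)      # 2 mm wobble
        rdot, c, _ = fit_constant_rdot(st.r, st.t)
        assert abs(distance_discrepancy(st, rdot, c)) <= 0.004


class TestMeanAcceleration:
    def test_direct_value(self, meta):
        t = np.array([0.0, 0.15, 0.3])
        st = StateSeries("m", t, np.ones(3), np.array([0.2, 0.35, 0.5]),
                         np.zeros(3), np.ones(3), meta)
        assert mean_acceleration(st) == pytest.approx(1.0)

    def test_accelerate_then_decelerate_net_positive(self, meta):
        t = np.linspace(0, 0.4, 50)
        V = 0.3 + 0.5 * np.sin(np.pi * t / 0.4) + 0.25 * t
        st = StateSeries("m", t, np.ones(50), V, np.zeros(50), V, meta)
        assert mean_acceleration(st) > 0

    def test_monotone_deceleration_negative(self, meta):
        t = np.linspace(0, 0.3, 30)
        V = 0.5 - 0.8 * t
        st = StateSeries("m", t, np.ones(30), V, np.zeros(30), V, meta)
        assert mean_acceleration(st) < 0

    def test_zero_duration_errors(self, meta):
        st = StateSeries("m", np.zeros(2), np.ones(2), np.ones(2),
                         np.zeros(2), np.ones(2), meta)
        with pytest.raises(ValueError):
            mean_acceleration(st)


class TestAccelErrorCorrelation:
    def test_noiseless_increasing_entry_is_strongly_correlated(self):
        st = simulate_constant_rdot(0.3, 1.0, 10.0, 0.2)
        r_star = st.r[-1]
        corr = accel_error_correlation(st, r_star, 10.0, c=1.0)
        assert corr > 0.99

    def test_steady_setpoint_is_flagged_undefined(self):
        st = simulate_constant_rdot(0.3, 2.0, 0.0, 0.3)
        corr = accel_error_correlation(st, 2.0, 0.0, c=2.0)
        assert np.isnan(corr)


class TestDecreasingEntries:
    def test_negative_step_always_decelerates(self):
        # dre < 0 implies braking throughout on noiseless constant-rdot motion
        for r_star, dre, y0 in [(1.5, -1.0, 0.2), (2.0, -0.5, 0.3), (1.0, -2.0, 0.15)]:
            r0 = r_star - dre
            dur = abs(dre) / 8.0
            st = simulate_constant_rdot(y0, r0, -8.0, dur)
            assert mean_acceleration(st) < 0

    def test_eq_identity_at_start_zero_step(self):
        # with dre = 0 the start acceleration reduces to rdot*y0 - r*^2*y0
        y0, r_star, rdot = 0.28, 2.0, 6.0
        st = simulate_constant_rdot(y0, r_star, rdot, 0.1)
        assert st.A[0] == pytest.approx(rdot * y0 - r_star**2 * y0, rel=1e-9)
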