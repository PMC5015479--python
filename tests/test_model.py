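"""Core model: target change, continuous simulation, Euler recursion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fluidshift as fs
from fluidshift.errors import (InputError, ParameterDomainError,
                               ScheduleRangeError)

from conftest import analytic_constant_infusion


class TestDomainTypes:
    @pytest.mark.parametrize("alpha,K,V_B0", [
        (0.0, 0.05, 4000), (-1, 0.05, 4000),
        (2, 0.0, 4000), (2, -0.1, 4000),
        (2, 0.05, 0.0), (2, 0.05, -500),
    ])
    def test_invalid_params_rejected(self, alpha, K, V_B0):
        with pytest.raises(ParameterDomainError):
            fs.ModelParams(alpha=alpha, K=K, V_B0=V_B0)

    def test_colloid_like_alpha_below_one_is_legal(self):
        fs.ModelParams(alpha=0.34, K=0.147, V_B0=3110.0)

    def test_schedule_validation(self):
        with pytest.raises(InputError):
            fs.InputSchedule(np.array([5.0]), np.array([1.0]),
                             np.array([0.0]), 10.0)  # must start at 0
        with pytest.raises(InputError):
            fs.InputSchedule(np.array([0.0, 0.0]), np.array([1.0, 1.0]),
                             np.array([0.0, 0.0]), 10.0)  # not increasing
        with pytest.raises(InputError):
            fs.InputSchedule(np.array([0.0]), np.array([-1.0]),
                             np.array([0.0]), 10.0)  # negative rate
        with pytest.raises(InputError):
            fs.InputSchedule(np.array([0.0, 30.0]), np.array([1.0, 0.0]),
                             np.array([0.0, 0.0]), 20.0)  # short duration

    def test_trace_validation(self):
        with pytest.raises(InputError):
            fs.VolumeTrace(np.array([0.0, 1.0, 1.0]), np.zeros(3))
        with pytest.raises(InputError):
            fs.VolumeTrace(np.array([0.0, 1.0]), np.array([0.0, -1.5]))

    def test_cumulative_net_is_exact_piecewise_integral(self):
        sch = fs.InputSchedule(np.array([0.0, 10.0, 40.0]),
                               np.array([30.0, 0.0, 5.0]),
                               np.array([0.0, 2.0, 2.0]), 100.0)
        assert sch.cumulative_net(5.0) == pytest.approx(150.0)
        assert sch.cumulative_net(10.0) == pytest.approx(300.0)
        assert sch.cumulative_net(40.0) == pytest.approx(300.0 - 60.0)
        assert sch.cumulative_net(100.0) == pytest.approx(240.0 + 3.0 * 60.0)


class TestTargetBloodVolumeChange:
    def test_zero_input_gives_zero(self):
        sch = fs.InputSchedule.constant(0.0, 0.0, 100.0)
        for alpha, t in [(0.5, 10.0), (3.0, 100.0)]:
            assert fs.target_blood_volume_change(sch, alpha, t) == 0.0

    @pytest.mark.parametrize("u,v,alpha,t,expected", [
        (30.0, 0.0, 2.0, 30.0, 300.0),   # (1/3)*900
        (20.0, 5.0, 3.0, 40.0, 150.0),   # (1/4)*600
    ])
    def test_constant_rate_examples(self, u, v, alpha, t, expected):
        sch = fs.InputSchedule.constant(u, v, 60.0)
        assert fs.target_blood_volume_change(sch, alpha, t) == pytest.approx(
            expected, rel=1e-12)

    def test_errors(self, constant_infusion):
        with pytest.raises(ScheduleRangeError):
            fs.target_blood_volume_change(constant_infusion, 2.0, 100.0)
        with pytest.raises(ParameterDomainError):
            fs.target_blood_volume_change(constant_infusion, -1.0, 10.0)


class TestSimulateResponse:
    def test_equilibrium_with_zero_input(self, typical_params):
        sch = fs.InputSchedule.constant(0.0, 0.0, 100.0)
        sim = fs.simulate_response(typical_params, sch, np.linspace(0, 100, 51))
        for arr in (sim.dVB, sim.q, sim.dVISF, sim.rB, sim.eB):
            assert np.all(arr == 0.0)

    def test_matches_closed_form_constant_infusion(self, typical_params,
                                                   constant_infusion):
        grid = np.linspace(0.0, 60.0, 241)
        sim = fs.simulate_response(typical_params, constant_infusion, grid)
        exact = analytic_constant_infusion(grid, 20.0, 2.0, 0.05)
        np.testing.assert_allclose(sim.dVB, exact, rtol=1e-10, atol=1e-10)
        # frozen spot value from the closed form
        i = np.searchsorted(grid, 30.0)
        assert sim.dVB[i] == pytest.approx(407.165, abs=0.001)

    def test_bolus_settles_at_target_fraction(self, typical_params,
                                              bolus_schedule):
        # 1500 ml bolus, alpha = 2: feedback drives e_B -> 0, steady state
        # retains U/(1+alpha) = 500 ml intravascularly
        grid = np.linspace(0.0, 600.0, 601)
        sim = fs.simulate_response(typical_params, bolus_schedule, grid)
        assert sim.dVB[-1] == pytest.approx(500.0, rel=1e-6)

    def test_result_internal_consistency(self, typical_params, bolus_schedule):
        grid = np.linspace(0.0, 600.0, 301)
        sim = fs.simulate_response(typical_params, bolus_schedule, grid)
        assert sim.dVB[0] == 0.0
        np.testing.assert_allclose(sim.vb_frac, sim.dVB / 4000.0, rtol=1e-14)
        np.testing.assert_allclose(sim.q, -0.05 * sim.eB, rtol=1e-14)
        np.testing.assert_allclose(sim.eB, sim.rB - sim.dVB, rtol=1e-12,
                                   atol=1e-12)

    def test_flow_sign_follows_discrepancy(self, typical_params,
                                           bolus_schedule):
        # fluid leaves the vasculature exactly when ΔV_B exceeds its target
        grid = np.linspace(0.0, 600.0, 601)
        sim = fs.simulate_response(typical_params, bolus_schedule, grid)
        mask = np.abs(sim.eB) > 1e-9
        assert np.all(np.sign(sim.q[mask]) == np.sign(-sim.eB[mask]))
        assert np.any(sim.q > 1e-6)  # infusion drives outward shift

    def test_grid_validation(self, typical_params, constant_infusion):
        with pytest.raises(InputError):
            fs.simulate_response(typical_params, constant_infusion, [])
        with pytest.raises(InputError):
            fs.simulate_response(typical_params, constant_infusion, [5.0, 10.0])
        with pytest.raises(ScheduleRangeError):
            fs.simulate_response(typical_params, constant_infusion,
                                 [0.0, 30.0, 90.0])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(scale=st.floats(0.25, 4.0), alpha=st.floats(0.3, 6.0),
           K=st.floats(0.01, 0.3))
    def test_linearity_in_the_inputs(self, scale, alpha, K):
        """Scaling u and v jointly scales ΔV_B pointwise (LTI model)."""
        params = fs.ModelParams(alpha=alpha, K=K, V_B0=5000.0)
        grid = np.linspace(0.0, 200.0, 81)
        base = fs.InputSchedule(np.array([0.0, 30.0]), np.array([40.0, 0.0]),
                                np.array([2.0, 2.0]), 200.0)
        scaled = fs.InputSchedule(base.breakpoints, base.u_rates * scale,
                                  base.v_rates * scale, base.duration)
        sim1 = fs.simulate_response(params, base, grid)
        sim2 = fs.simulate_response(params, scaled, grid)
        np.testing.assert_allclose(sim2.dVB, scale * sim1.dVB,
                                   rtol=1e-9, atol=1e-9)


class TestInterstitialReconstruction:
    def test_zero_input_gives_zero_series(self, typical_params):
        sch = fs.InputSchedule.constant(0.0, 0.0, 50.0)
        sim = fs.simulate_response(typical_params, sch, np.linspace(0, 50, 26))
        assert np.all(fs.reconstruct_interstitial_change(sim) == 0.0)

    @pytest.mark.parametrize("alpha", [0.45, 2.0, 3.0])
    def test_steady_state_ratio_equals_alpha(self, alpha):
        params = fs.ModelParams(alpha=alpha, K=0.05, V_B0=4000.0)
        sch = fs.InputSchedule(np.array([0.0, 30.0]), np.array([50.0, 0.0]),
                               np.array([0.0, 0.0]), 10.0 / 0.05 + 30.0)
        grid = np.linspace(0.0, sch.duration, 1001)
        sim = fs.simulate_response(params, sch, grid)
        ratio = sim.dVISF[-1] / sim.dVB[-1]
        assert ratio == pytest.approx(alpha, rel=0.01)

    def test_conservation_of_net_input(self, typical_params):
        sch = fs.InputSchedule(np.array([0.0, 30.0, 60.0]),
                               np.array([50.0, 0.0, 10.0]),
                               np.array([1.0, 1.0, 1.0]), 300.0)
        grid = np.linspace(0.0, 300.0, 601)
        sim = fs.simulate_response(typical_params, sch, grid)
        net = np.asarray(sch.cumulative_net(grid))
        err = np.abs(sim.dVB + sim.dVISF - net)
        assert np.max(err) <= 0.005 * sch.total_infused()


class TestDifferenceEquation:
    def test_zero_input_stays_zero(self, typical_params):
        sch = fs.InputSchedule.constant(0.0, 0.0, 100.0)
        tr = fs.simulate_difference_equation(typical_params, sch, 1.0, 50)
        assert np.all(tr.vb_frac == 0.0)

    def test_fine_step_matches_closed_form(self, typical_params,
                                           constant_infusion):
        tr = fs.simulate_difference_equation(typical_params, constant_infusion,
                                             0.1, 300)
        exact = analytic_constant_infusion(30.0, 20.0, 2.0, 0.05) / 4000.0
        assert tr.vb_frac[-1] == pytest.approx(exact, rel=0.01)

    def test_first_order_convergence(self, typical_params, constant_infusion):
        steps = [4.0, 2.0, 1.0, 0.5]
        errors = []
        for ts in steps:
            n = int(round(32.0 / ts))
            tr = fs.simulate_difference_equation(typical_params,
                                                 constant_infusion, ts, n)
            exact = analytic_constant_infusion(tr.times, 20.0, 2.0,
                                               0.05) / 4000.0
            errors.append(np.max(np.abs(tr.vb_frac - exact)))
        order = np.polyfit(np.log(steps), np.log(errors), 1)[0]
        assert 0.8 <= order <= 1.2
        # halving T_S approximately halves the worst-case deviation
        ratios = np.array(errors[:-1]) / np.array(errors[1:])
        assert np.all((1.5 < ratios) & (ratios < 2.5))

    def test_stability_margin_warning(self, constant_infusion):
        params = fs.ModelParams(alpha=2.0, K=0.5, V_B0=4000.0)
        with pytest.warns(UserWarning, match="K\\*T_S"):
            fs.simulate_difference_equation(params, constant_infusion, 4.0, 10)

    def test_input_validation(self, typical_params, constant_infusion):
        with pytest.raises(InputError):
            fs.simulate_difference_equation(typical_params, constant_infusion,
                                            0.0, 10)
        with pytest.raises(InputError):
            fs.simulate_difference_equation(typical_params, constant_infusion,
                                            1.0, 2)
        with pytest.raises(ScheduleRangeError):
            fs.simulate_difference_equation(typical_params, constant_infusion,
                                            10.0, 100)
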