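"""Unit and property tests for the model components and their reduction."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import glucoloop as gl
from glucoloop.model import NoEquilibriumError, _refine_peak
from glucoloop.params import LumpedParams, MealSpec, ModelParams


class TestMealInflow:
    def test_vanishes_at_origin_for_shape_above_one(self, meal):
        assert gl.meal_inflow(0.0, meal) == 0.0

    def test_negative_time_rejected(self, meal):
        with pytest.raises(ValueError):
            gl.meal_inflow(-0.1, meal)

    def test_integral_equals_meal_glucose(self, meal):
        total, _ = quad(lambda t: gl.meal_inflow(t, meal), 0.0, 24.0)
        assert total == pytest.approx(meal.w, rel=1e-6)

    def test_mode_matches_closed_form(self, meal):
        # closed-form Gamma mode (a-1)/k, confirmed by grid search
        grid = np.linspace(1e-6, 3.0, 30001)
        t_star = grid[np.argmax(gl.meal_inflow(grid, meal))]
        assert t_star == pytest.approx((meal.a - 1) / meal.k, abs=2e-4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(w=st.floats(0.0, 1e3), a=st.floats(1.05, 20.0),
           k=st.floats(0.1, 20.0), t=st.floats(0.0, 48.0))
    def test_nonnegative_everywhere(self, w, a, k, t):
        assert gl.meal_inflow(t, MealSpec(w=w, a=a, k=k)) >= 0.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(w=st.floats(1.0, 1e3), a=st.floats(1.1, 12.0), k=st.floats(0.5, 12.0))
    def test_normalization_for_admissible_meals(self, w, a, k):
        meal = MealSpec(w=w, a=a, k=k)
        total, _ = quad(lambda t: gl.meal_inflow(t, meal), 0.0, np.inf)
        assert total == pytest.approx(w, rel=1e-6)


class TestExpenditure:
    def test_zero_at_threshold(self, healthy):
        assert gl.expenditure(healthy.x0, healthy) == 0.0

    def test_fraction_near_one_at_high_glucose(self, healthy):
        assert gl.expenditure(10.0, healthy) / healthy.q == pytest.approx(
            0.99, abs=0.005)

    def test_value_at_typical_baseline(self, healthy):
        # independent scalar computation: 100*(1 - exp(-0.7*1.8))
        expected = 100.0 * (1.0 - np.exp(-0.7 * 1.8))
        assert gl.expenditure(4.8, healthy) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(71.6, abs=0.05)

    def test_monotone_increasing_and_bounded(self, healthy):
        x = np.linspace(0.5, 30.0, 200)
        e = gl.expenditure(x, healthy)
        assert np.all(np.diff(e) > 0)
        assert np.all(e < healthy.q)

    def test_signed_below_threshold(self, healthy):
        # deliberately unclamped: the negative branch pushes glucose back up
        assert gl.expenditure(2.0, healthy) < 0.0


class TestDrives:
    @pytest.mark.parametrize("x,expected", [(2.5, 0.0), (3.0, 0.0), (4.8, 1.8)])
    def test_insulin_drive_piecewise(self, x, expected):
        assert gl.insulin_drive(x, 3.0) == pytest.approx(expected, abs=1e-12)

    def test_glucagon_drive_limits(self):
        assert gl.glucagon_drive(0.0, 50.0) == 1.0
        assert gl.glucagon_drive(50.0, 50.0) == pytest.approx(np.exp(-1))

    def test_glucagon_drive_lumped_form(self):
        # exp(-b/n) with b=1.8, n=1.75
        assert gl.glucagon_drive(1.8, 1.75) == pytest.approx(
            np.exp(-1.8 / 1.75), rel=1e-12)

    def test_glucagon_drive_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            gl.glucagon_drive(1.0, 0.0)


class TestFullSystem:
    def test_equilibrium_is_fixed_point(self):
        params = ModelParams()
        lumped = gl.reduce_params(params)
        xb = gl.baseline(lumped)
        b = max(0.0, xb - params.x0)
        y = params.beta * b / params.lambda_y
        z = (params.alpha * gl.glucagon_drive(params.beta * b, params.m)
             / params.gamma_z)
        deriv = gl.full_rhs(0.0, (xb, y, z), params)
        assert np.all(np.abs(deriv) < 1e-9)

    def test_hormone_equations_below_threshold(self):
        params = ModelParams()
        _, dy, dz = gl.full_rhs(0.0, (2.0, 5.0, 7.0), params)
        assert dy == pytest.approx(-params.lambda_y * 5.0)
        assert dz == pytest.approx(params.alpha - params.gamma_z * 7.0)

    def test_infusion_enters_insulin_equation(self):
        params = ModelParams()
        free = gl.full_rhs(0.0, (6.0, 5.0, 7.0), params)
        infused = gl.full_rhs(0.0, (6.0, 5.0, 7.0), params,
                              infusion=lambda t, x: 12.0)
        assert infused[1] - free[1] == pytest.approx(12.0)
        assert infused[0] == free[0] and infused[2] == free[2]


class TestReduction:
    def test_lumping_formulas(self):
        params = ModelParams(delta=2.0, beta=34.9, lambda_y=8.3)
        lumped = gl.reduce_params(params)
        assert lumped.omega == pytest.approx(2.0 * 34.9 / 8.3)
        assert lumped.omega == pytest.approx(8.41, abs=0.01)
        assert lumped.kappa == pytest.approx(0.241, abs=0.001)

    def test_consistency_invariants(self):
        params = ModelParams()
        lumped = gl.reduce_params(params)
        assert lumped.omega * params.lambda_y == pytest.approx(
            params.delta * params.beta, rel=1e-12)
        assert lumped.sigma * params.gamma_z == pytest.approx(
            params.alpha * params.epsilon, rel=1e-12)

    def test_round_trip_through_disaggregation(self, healthy):
        params = gl.disaggregate(healthy)
        back = gl.reduce_params(params)
        for f in dataclasses.fields(LumpedParams):
            assert getattr(back, f.name) == pytest.approx(
                getattr(healthy, f.name), rel=1e-12)

    def test_inverse_map_recovers_printed_delta(self):
        # delta = omega*lambda/beta at the fitted omega, printed as 2
        delta = 8.30 * 8.3 / 34.9
        assert round(delta) == 2

    def test_beta_zero_signalled(self):
        with pytest.raises(ValueError, match="beta"):
            gl.reduce_params(dataclasses.replace(ModelParams(), beta=0.0))


class TestReducedRhs:
    def test_zero_at_baseline(self, healthy):
        xb = gl.baseline(healthy)
        assert abs(gl.reduced_rhs(0.0, xb, healthy)) < 1e-9

    def test_matches_independent_transcription(self, healthy):
        # separately-coded scalar form of the reduced equation
        rng = np.random.default_rng(42)
        for _ in range(1000):
            x = rng.uniform(0.5, 15.0)
            om = rng.uniform(0.5, 30.0)
            sg = rng.uniform(0.0, 2000.0)
            lp = LumpedParams(omega=om, sigma=sg, n=1.75, kappa=0.2)
            b = x - 3.0 if x > 3.0 else 0.0
            expected = (-100.0 * (1.0 - np.exp(-0.7 * (x - 3.0)))
                        - om * b * x + sg * np.exp(-b / 1.75))
            got = gl.reduced_rhs(0.0, x, lp)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_pushes_up_below_threshold_without_glucagon(self):
        lp = LumpedParams(omega=8.3, sigma=0.0, n=1.75, kappa=0.0)
        assert gl.reduced_rhs(0.0, 2.5, lp) > 0.0


class TestBaseline:
    def test_fitted_preset_near_printed_value(self, healthy):
        assert gl.baseline(healthy) == pytest.approx(4.8, abs=0.1)

    def test_residual_below_tolerance(self, healthy):
        xb = gl.baseline(healthy)
        assert abs(gl.reduced_rhs(0.0, xb, healthy)) < 1e-10

    def test_sigma_zero_equilibrium_at_threshold(self):
        lp = LumpedParams(omega=8.3, sigma=0.0, n=1.75, kappa=0.0)
        assert gl.baseline(lp) == lp.x0

    def test_strictly_decreasing_in_omega(self, healthy):
        doubled = dataclasses.replace(healthy, omega=2 * healthy.omega)
        assert gl.baseline(doubled) < gl.baseline(healthy)

    def test_no_equilibrium_is_explicit(self):
        lp = LumpedParams(omega=0.0, sigma=1e9, n=1.75, kappa=0.0)
        with pytest.raises(NoEquilibriumError):
            gl.baseline(lp)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(om=st.floats(0.5, 30.0), sg=st.floats(10.0, 2000.0))
    def test_baseline_lies_above_threshold(self, om, sg):
        lp = LumpedParams(omega=om, sigma=sg, n=1.75, kappa=0.0)
        xb = gl.baseline(lp)
        assert lp.x0 < xb <= 12.0


class TestSimulate:
    def test_no_meal_stays_at_baseline(self, healthy):
        traj = gl.simulate(healthy, meal=None, horizon=24.0)
        assert np.max(np.abs(traj.glucose - traj.baseline)) < 1e-6

    def test_zero_meal_equivalent_to_none(self, healthy):
        traj = gl.simulate(healthy, MealSpec(w=0.0, a=4.11, k=5.69),
                           horizon=6.0)
        assert np.max(np.abs(traj.glucose - traj.baseline)) < 1e-6

    def test_returns_to_baseline_after_meal(self, healthy, meal):
        traj = gl.simulate(healthy, meal, horizon=24.0)
        assert abs(traj.glucose[-1] - traj.baseline) < 0.05

    def test_peak_monotone_in_meal_size(self, healthy):
        peaks = [gl.simulate(healthy, MealSpec(w=w, a=4.11, k=5.69)).peak_value
                 for w in (100.0, 200.0, 300.0, 400.0)]
        assert np.all(np.diff(peaks) > 0)

    def test_peak_monotone_in_omega(self, healthy, meal):
        peaks = [gl.simulate(dataclasses.replace(healthy, omega=om),
                             meal).peak_value
                 for om in (2.0, 4.0, 8.3, 16.0)]
        assert np.all(np.diff(peaks) < 0)

    def test_summary_features_consistent(self, healthy_trajectory):
        tr = healthy_trajectory
        # parabolic refinement may only raise the grid maximum slightly
        assert tr.peak_value >= tr.glucose.max() - 1e-12
        assert tr.peak_value - tr.glucose.max() < 0.01
        assert abs(tr.peak_time - tr.times[tr.glucose.argmax()]) <= 1.0 / 60.0

    def test_rejects_nonpositive_horizon(self, healthy):
        with pytest.raises(ValueError):
            gl.simulate(healthy, horizon=0.0)

    def test_peak_refinement_on_parabola(self):
        t = np.linspace(0.0, 2.0, 201)
        v = -3.0 * (t - 1.005) ** 2 + 7.0
        value, time = _refine_peak(t, v)
        assert value == pytest.approx(7.0, abs=1e-10)
        assert time == pytest.approx(1.005, abs=1e-10)


class TestQssGap:
    def test_gap_shrinks_with_time_scale_separation(self, healthy, meal):
        params = gl.disaggregate(healthy)
        gaps = [gl.qss_gap(params, meal, s) for s in (1.0, 10.0, 100.0)]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.05

    def test_co_scaling_preserves_lumped_parameters(self, healthy):
        params = gl.disaggregate(healthy)
        for s in (1.0, 10.0, 100.0):
            scaled = dataclasses.replace(
                params, lambda_y=params.lambda_y * s, beta=params.beta * s,
                alpha=params.alpha * s, gamma_z=params.gamma_z * s,
                m=params.m * s)
            back = gl.reduce_params(scaled)
            assert back.omega == pytest.approx(healthy.omega, rel=1e-12)
            assert back.sigma == pytest.approx(healthy.sigma, rel=1e-12)
            assert back.n == pytest.approx(healthy.n, rel=1e-12)

    def test_insulin_tracks_quasi_steady_state(self, healthy, meal):
        params = gl.disaggregate(healthy)
        full = gl.simulate_full(params, meal, horizon=8.0)
        after_peak = full.times > full.peak_time
        b = np.maximum(0.0, full.glucose[after_peak] - params.x0)
        qss = params.beta * b / params.lambda_y
        mask = qss > 1.0  # compare where insulin is appreciably above zero
        ratio = full.insulin[after_peak][mask] / qss[mask]
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)
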