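"""Tests for the objective, adjoint system, control update and the
forward-backward sweep solver."""

import numpy as np
import pytest

import statswitch as sw
from statswitch import _kernels
from statswitch.model import default_initial_state
from statswitch.optimal_control import (
    ControlProblem,
    ControlWeights,
    STRATEGY_I_WEIGHTS,
    STRATEGY_II_WEIGHTS,
    control_update,
    forward_backward_sweep,
    objective_arrays,
)


@pytest.fixture(scope="module")
def problem(params, thresholds):
    return ControlProblem(
        params=params,
        thresholds=thresholds,
        ic=default_initial_state(params),
        weights=STRATEGY_II_WEIGHTS,
        n_steps=1500,
    )


class TestObjective:
    def test_zero_states_zero_controls_zero_cost(self):
        w = ControlWeights(1, 1, 0, 1, 1, 1, 1, T_bar=0.0, t_e=10.0)
        t = np.linspace(0, 10, 101)
        states = np.zeros((101, 8))
        assert objective_arrays(t, states, np.zeros(101), np.zeros(101), w) == 0.0

    def test_constant_tumour_analytic_integral(self):
        w = ControlWeights(1, 0, 0, 0, 0, 0, 0, T_bar=0.0, t_e=30.0)
        t = np.linspace(0, 30, 301)
        states = np.zeros((301, 8))
        states[:, 4] = 1.0
        assert objective_arrays(t, states, np.zeros(301), np.zeros(301), w) == (
            pytest.approx(30.0)
        )

    def test_bax_reward_lowers_cost(self):
        t = np.linspace(0, 30, 301)
        states = np.zeros((301, 8))
        states[:, 3] = 0.5
        w0 = ControlWeights(0, 0, 0, 0, 0, 0, 0, T_bar=0.0)
        w3 = ControlWeights(0, 0, 4, 0, 0, 0, 0, T_bar=0.0)
        u = np.zeros(301)
        assert objective_arrays(t, states, u, u, w3) < objective_arrays(t, states, u, u, w0)

    def test_grid_must_cover_horizon(self):
        w = ControlWeights(1, 0, 0, 0, 0, 0, 0, T_bar=0.0, t_e=30.0)
        t = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            objective_arrays(t, np.zeros((11, 8)), np.zeros(11), np.zeros(11), w)


class TestAdjoint:
    def _hamiltonian(self, y, lam, u, problem):
        """Running cost + lambda . f, with the smoothed switch."""
        p = _kernels.pack_params(problem.params, problem.thresholds)
        w = problem.weights
        f = _kernels.rhs8(y, u[0], u[1], p, _kernels.SMOOTH, problem.smooth_k)
        L = (w.A1 * (y[4] - w.T_bar) ** 2 + w.A2 * y[2] ** 2 - w.A3 * y[3] ** 2
             + w.C1 * u[0] + w.C2 * u[1] + w.C3 * u[0] ** 2 + w.C4 * u[1] ** 2)
        return L + lam @ f

    def test_matches_finite_difference_hamiltonian_gradient(self, problem, rng):
        """Analytic -dH/dx agrees with central differences at 200 random
        admissible points to 1e-6."""
        eps = 1e-6
        worst = 0.0
        for _ in range(200):
            y = rng.uniform(0.05, 4.0, 8)
            y[4] = rng.uniform(0.1, 5.0)
            lam = rng.uniform(-2.0, 2.0, 8)
            u = rng.uniform(0.0, 10.0, 2)
            analytic = sw.adjoint_rhs(y, lam, 0.0, problem)
            fd = np.empty(8)
            for i in range(8):
                yp, ym = y.copy(), y.copy()
                yp[i] += eps
                ym[i] -= eps
                fd[i] = -(self._hamiltonian(yp, lam, u, problem)
                          - self._hamiltonian(ym, lam, u, problem)) / (2 * eps)
            worst = max(worst, np.max(np.abs(analytic - fd)))
        assert worst < 1e-6

    def test_zero_weights_give_zero_costates(self, params, thresholds):
        w = ControlWeights(0, 0, 0, 0, 0, 1e-9, 1e-9, T_bar=0.0)
        pr = ControlProblem(params=params, thresholds=thresholds,
                            ic=default_initial_state(params), weights=w,
                            n_steps=500)
        p = _kernels.pack_params(params, thresholds)
        Y = np.tile(default_initial_state(params).as_array(), (501, 1))
        L = _kernels.rk4_backward(Y, pr.dt, p, _kernels.SMOOTH, 100.0,
                                  0.0, 0.0, 0.0, 0.0)
        assert np.max(np.abs(L)) == 0.0

    def test_ddp_costate_decouples_without_jak_degradation(self, params, thresholds):
        """With gammaD = 0 the DDP costate receives no feedback from the
        signalling states."""
        p0 = params.replace(gammaD=0.0)
        pr = ControlProblem(params=p0, thresholds=thresholds,
                            ic=default_initial_state(p0),
                            weights=STRATEGY_II_WEIGHTS, n_steps=500)
        y = default_initial_state(p0).as_array()
        lam = np.array([0.3, -0.2, 0.5, -0.1, 1.0, 0.2, -0.4, 0.0])
        d = sw.adjoint_rhs(y, lam, 0.0, pr)
        # lambda_D' = -dH/dD = muD * lambda_D (= 0 here since lambda_D = 0)
        assert d[7] == pytest.approx(0.0, abs=1e-12)


class TestControlUpdate:
    def test_boundary_stationarity(self):
        w = STRATEGY_II_WEIGHTS
        lam = np.full(5, -w.C1)
        m = np.ones(5, bool)
        u_S, _ = control_update(lam, lam, w, (50.0, 100.0), (m, m))
        np.testing.assert_array_equal(u_S, np.zeros(5))

    def test_clipping_at_upper_bound(self):
        w = STRATEGY_II_WEIGHTS
        lam = np.full(5, -1e9)
        m = np.ones(5, bool)
        u_S, _ = control_update(lam, lam, w, (50.0, 100.0), (m, m))
        np.testing.assert_array_equal(u_S, np.full(5, 50.0))

    def test_doubling_quadratic_weight_halves_interior_control(self):
        w1 = ControlWeights(1, 0, 0, 0.02, 0, 0.02, 0.01, T_bar=0.0)
        w2 = ControlWeights(1, 0, 0, 0.02, 0, 0.04, 0.01, T_bar=0.0)
        lam = np.array([-0.5, -1.0, -2.0])
        m = np.ones(3, bool)
        u1, _ = control_update(lam, lam, w1, (1e9, 1e9), (m, m))
        u2, _ = control_update(lam, lam, w2, (1e9, 1e9), (m, m))
        np.testing.assert_allclose(u1, 2 * u2)

    def test_zero_quadratic_weight_for_active_control_rejected(self, params, thresholds):
        w = ControlWeights(1, 0, 0, 0.02, 0, 0.0, 0, T_bar=0.0)
        with pytest.raises(ValueError, match="quadratic"):
            ControlProblem(params=params, thresholds=thresholds,
                           ic=default_initial_state(params), weights=w)


class TestSweep:
    def test_pure_cost_minimization_returns_zero_control(self, params, thresholds):
        w = ControlWeights(0, 0, 0, 0.02, 0, 0.02, 0, T_bar=0.0)
        pr = ControlProblem(params=params, thresholds=thresholds,
                            ic=default_initial_state(params), weights=w,
                            n_steps=500)
        sol = forward_backward_sweep(pr, max_iter=50)
        assert sol.converged
        assert np.max(sol.u_S) == 0.0

    def test_deterministic_repeat(self, problem):
        a = forward_backward_sweep(problem, max_iter=40)
        b = forward_backward_sweep(problem, max_iter=40)
        np.testing.assert_array_equal(a.u_S, b.u_S)
        assert a.iterations.equals(b.iterations)

    def test_monotone_objective_log(self, problem):
        sol = forward_backward_sweep(problem, max_iter=60)
        obj = sol.iterations.objective.values
        assert np.all(np.diff(obj) <= 1e-12)

    def test_controls_respect_bounds_and_masks(self, params, thresholds):
        res = sw.run_strategy_II(params, "SSSDDD",
                                 sweep_kwargs=dict(max_iter=60))
        sol = res["solution"]
        opt = sol.meta["opt_u_S"]
        t = sol.t
        assert np.all(opt >= 0) and np.all(opt <= 50.0)
        assert np.all(opt[t >= 15.0] == 0.0)  # off the S-slot mask


@pytest.fixture(scope="module")
def strategy_II_solution(params):
    return sw.run_strategy_II(params, "SSSDDD")


@pytest.fixture(scope="module")
def strategy_I_runs(params):
    return sw.run_strategy_I(params, sweep_kwargs=dict(max_iter=300))


class TestStrategyII:
    def test_beats_random_equal_total_profiles(self, params, thresholds,
                                               strategy_II_solution, rng):
        """The converged objective is no worse than 50 random admissible
        profiles delivering the same accumulated IFN-beta."""
        sol = strategy_II_solution["solution"]
        pr = ControlProblem(params=params, thresholds=thresholds,
                            ic=default_initial_state(params),
                            weights=STRATEGY_II_WEIGHTS, n_steps=3000)
        p = _kernels.pack_params(params, thresholds)
        t = pr.t
        mask = t < 15.0
        total = sol.total_S
        uD_half = pr.background("D")
        from statswitch.dosing import PulseControl, PulseSchedule, build_pulse_controls
        sched = PulseSchedule(sequence="SSSDDD", u_S_rate=0.0, u_D_rate=46.0)
        _, uD = build_pulse_controls(sched)
        from statswitch.model import _sample_half_grid
        uD_half = _sample_half_grid(uD, t)
        y0 = default_initial_state(params).as_array()
        worse = 0
        for _ in range(50):
            raw = rng.uniform(0.0, 1.0, len(t)) * mask
            raw *= total / np.trapezoid(raw, t)
            half = np.empty(2 * (len(t) - 1) + 1)
            half[0::2] = raw
            half[1::2] = 0.5 * (raw[:-1] + raw[1:])
            Y = _kernels.rk4_forward(y0, half, uD_half, pr.dt, p,
                                     _kernels.SMOOTH, 100.0)
            J = objective_arrays(t, Y, raw, uD_half[0::2], STRATEGY_II_WEIGHTS)
            if J >= sol.objective:
                worse += 1
        assert worse == 50

    def test_interior_stationarity_at_convergence(self, strategy_II_solution):
        """|dH/du| is small on interior arcs and pushes outward at bounds."""
        sol = strategy_II_solution["solution"]
        w = STRATEGY_II_WEIGHTS
        u = sol.meta["opt_u_S"]
        grad = w.C1 + 2 * w.C3 * u + sol.adjoint[:, 5]
        mask = sol.t < 15.0
        interior = mask & (u > 1e-4) & (u < 50.0 - 1e-4)
        assert np.max(np.abs(grad[interior])) < 0.02
        at_zero = mask & (u <= 1e-4)
        if at_zero.any():
            assert np.min(grad[at_zero]) > -0.05  # no profitable increase

    def test_all_ddp_scheme_accumulates_nothing(self, params):
        res = sw.run_strategy_II(params, "DDDDDD",
                                 sweep_kwargs=dict(max_iter=30))
        assert res["accumulated_S"] == pytest.approx(0.0, abs=1e-9)

    def test_reduction_is_relative_to_untreated_control(self, params, thresholds,
                                                        strategy_II_solution):
        ctrl = sw.simulate(params, thresholds, default_initial_state(params),
                           (0.0, 30.0), method="rk4")
        expected = 100 * (1 - strategy_II_solution["final_T"] / ctrl["T"][-1])
        assert strategy_II_solution["reduction_pct"] == pytest.approx(expected)


class TestStrategyI:
    def test_optimal_beats_reference_profiles(self, strategy_I_runs):
        opt = strategy_I_runs["optimal"]["objective"]
        assert opt <= strategy_I_runs["constant"]["objective"]
        assert opt <= strategy_I_runs["alternating"]["objective"]

    def test_final_volume_ordering(self, strategy_I_runs):
        r = strategy_I_runs
        assert (r["optimal"]["final_T"] < r["constant"]["final_T"]
                < r["alternating"]["final_T"])

    def test_reference_totals_are_equalized(self, strategy_I_runs):
        r = strategy_I_runs
        assert r["alternating"]["total_S"] == pytest.approx(
            r["constant"]["total_S"], rel=1e-4)
        assert r["alternating"]["total_D"] == pytest.approx(
            r["constant"]["total_D"], rel=1e-4)

    def test_cumulative_doses_nondecreasing(self, strategy_I_runs):
        sol = strategy_I_runs["optimal"]["solution"]
        cum_S = np.cumsum(sol.u_S)
        cum_D = np.cumsum(sol.u_D)
        assert np.all(np.diff(cum_S) >= 0) and np.all(np.diff(cum_D) >= 0)

    def test_switch_smoothing_does_not_change_outcome(self, params, thresholds,
                                                      strategy_I_runs):
        """The optimized profile's final tumour volume agrees between the
        sharp-switch and smoothed-switch forward models within 2%."""
        sol = strategy_I_runs["optimal"]["solution"]
        sharp_T = strategy_I_runs["optimal"]["final_T"]
        smooth_T = float(sol.states[-1, 4])
        assert smooth_T == pytest.approx(sharp_T, rel=0.02)


class TestHalfLife:
    def test_slower_decay_always_helps_and_optimal_is_least_sensitive(self, params):
        df = sw.half_life_experiment(params, (5.5, 4.8, 3.2), n_steps=1500,
                                     sweep_kwargs=dict(max_iter=200))
        piv = df.pivot(index="muS", columns="strategy", values="final_T")
        for strat in ("alternating", "constant", "optimal"):
            assert piv.loc[3.2, strat] < piv.loc[5.5, strat]
        spread = piv.max() - piv.min()
        assert spread["optimal"] < spread["alternating"]
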