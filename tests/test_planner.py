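import numpy as np
import pytest
from scipy.integrate import solve_ivp

import sffc.arm as arm
from sffc.arm import ArmParams, NoiseParams
from sffc import planner as pl
from sffc._codegen import get_derivatives

from conftest import make_nw_spec, COARSE
from helpers import euler_maruyama_ensemble, min_effort_cost_linear


class TestPropagation:
    def test_noiseless_degenerates_to_deterministic_ode(self, nw_spec):
        params = nw_spec.params
        U = pl._min_jerk_guess(nw_spec, 0.6)
        t, m, P = pl.propagate_mean_cov(
            U, nw_spec.x0, np.zeros((6, 6)), params,
            NoiseParams.symmetric(0.0, 0.0), 0.6, n_steps=120)
        assert np.max(np.abs(P)) == 0.0
        s_nodes = np.linspace(0.0, 0.6, len(U))

        def u_of_t(tq):
            return np.array([np.interp(tq, s_nodes, U[:, k]) for k in range(2)])

        sol = solve_ivp(lambda tq, x: arm.drift(x, u_of_t(tq), params),
                        [0, 0.6], nw_spec.x0, t_eval=t, rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(sol.y.T - m)) < 1e-6

    def test_torque_variance_grows_linearly_with_zero_control(self, nw_spec):
        # the torque rows are driven by pure additive noise: exact closed form
        noise = NoiseParams.symmetric(0.005, 0.01)
        U = np.zeros((5, 2))
        T = 0.8
        t, m, P = pl.propagate_mean_cov(U, nw_spec.x0, np.zeros((6, 6)),
                                        nw_spec.params, noise, T, n_steps=80)
        assert np.allclose(P[:, 4, 4], 0.005 ** 2 * t, rtol=1e-10, atol=1e-16)
        assert np.allclose(P[:, 5, 5], 0.005 ** 2 * t, rtol=1e-10, atol=1e-16)
        assert np.allclose(P[:, 4, 5], 0.0, atol=1e-16)

    def test_moments_match_monte_carlo(self, nw_spec):
        """Second-order moment closure vs 1e5 SDE rollouts (3-SE agreement)."""
        T = 1.0
        U = pl._min_jerk_guess(nw_spec, T)
        t, m, P = pl.propagate_mean_cov(U, nw_spec.x0, np.zeros((6, 6)),
                                        nw_spec.params, nw_spec.noise, T,
                                        n_steps=200)
        n = 100_000
        xT = euler_maruyama_ensemble(nw_spec.x0, U, T, nw_spec.params,
                                     nw_spec.noise, n, dt=0.005, seed=42)
        se_mean = xT.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.all(np.abs(xT.mean(axis=0) - m[-1]) < 3 * se_mean)
        hand = arm.forward_kinematics(xT[:, :2], nw_spec.params)
        tr_mc = np.trace(np.cov(hand.T))
        J = arm.jacobian(m[-1][:2], nw_spec.params)
        tr_prop = np.trace(J @ P[-1][:2, :2] @ J.T)
        se_tr = tr_mc * np.sqrt(2.0 / (n - 1))
        assert abs(tr_mc - tr_prop) < 3 * se_tr

    def test_covariance_symmetric_psd_along_plan(self, free_plan_coarse):
        P = free_plan_coarse.P
        assert np.allclose(P, np.swapaxes(P, -1, -2))
        evals = np.linalg.eigvalsh(P)
        assert evals.min() >= -1e-10


class TestTerminalVarianceCost:
    def test_zero_covariance(self):
        assert pl.terminal_variance_cost(np.zeros(6), np.zeros((6, 6)),
                                         ArmParams()) == 0.0

    def test_identity_jacobian_reduces_to_trace(self):
        # configuration where J = I does not exist for this arm; check the
        # algebra directly through a sampling oracle instead
        params = ArmParams()
        rng = np.random.default_rng(7)
        q = rng.uniform(0.3, 1.5, 2)
        A = rng.normal(size=(2, 2))
        Pq = A @ A.T * 1e-4
        PT = np.zeros((6, 6))
        PT[:2, :2] = Pq
        mT = np.concatenate([q, np.zeros(4)])
        phi = pl.terminal_variance_cost(mT, PT, params)
        dq = rng.multivariate_normal(np.zeros(2), Pq, size=1_000_000)
        dhand = dq @ arm.jacobian(q, params).T
        mc = np.trace(np.cov(dhand.T))
        assert phi == pytest.approx(mc, rel=5e-3)

    def test_diagonal_case_sums_scaled_variances(self):
        params = ArmParams()
        mT = np.array([0.8, 1.2, 0, 0, 0, 0])
        J = arm.jacobian(mT[:2], params)
        PT = np.zeros((6, 6))
        PT[0, 0], PT[1, 1] = 3e-4, 5e-4
        expected = np.trace(J @ np.diag([3e-4, 5e-4]) @ J.T)
        assert pl.terminal_variance_cost(mT, PT, params) == pytest.approx(expected)


class TestRunningCost:
    def test_zero_control_stationary_mean(self):
        t = np.linspace(0, 1, 50)
        m = np.tile(np.array([0.9, 1.7, 0, 0, 0, 0]), (50, 1))
        u = np.zeros((50, 2))
        assert pl.running_cost(t, m, u, alpha=0.5) == 0.0

    def test_constant_control_effort_integral(self):
        t = np.linspace(0, 1, 201)
        m = np.tile(np.array([0.9, 1.7, 0, 0, 0, 0]), (201, 1))
        u = np.tile([1.0, 2.0], (201, 1))
        assert pl.running_cost(t, m, u, alpha=0.0) == pytest.approx(5.0)

    def test_analytic_hand_jerk_matches_finite_differences(self):
        params = ArmParams()
        deriv = get_derivatives(params)
        x0 = np.array([0.9, 1.7, 0.1, -0.2, 0.3, 0.1])
        u = np.array([1.0, -0.5])
        tq = np.linspace(0, 0.02, 401)
        sol = solve_ivp(lambda t, x: arm.drift(x, u, params), [0, 0.02], x0,
                        t_eval=tq, rtol=1e-12, atol=1e-12)
        hand = arm.forward_kinematics(sol.y[:2].T, params)
        h = tq[1] - tq[0]
        mid = 200
        j_fd = (hand[mid + 2] - 2 * hand[mid + 1]
                + 2 * hand[mid - 1] - hand[mid - 2]) / (2 * h ** 3)
        j2 = deriv.hand_jerk_sq(sol.y[:, mid], u)
        assert j2 == pytest.approx(np.sum(j_fd ** 2), rel=1e-3)


class TestSolvers:
    def test_terminal_constraints_met_to_tolerance(self, free_plan):
        spec = free_plan.spec
        hand_T = arm.forward_kinematics(free_plan.m[-1][:2], spec.params)
        assert np.max(np.abs(hand_T - spec.target)) < 1e-6
        assert np.max(np.abs(free_plan.m[-1][2:4])) < 1e-6
        assert np.max(np.abs(free_plan.m[-1][4:6])) < 1e-6

    def test_deterministic_reduction_is_mesh_converged(self):
        spec = make_nw_spec(r=0.0, noise=NoiseParams.symmetric(0.0, 0.0),
                            **COARSE)
        plan1 = pl.solve_fixed_time(spec, 0.7)
        spec2 = make_nw_spec(r=0.0, noise=NoiseParams.symmetric(0.0, 0.0),
                             n_controls=2 * COARSE["n_controls"] - 1,
                             n_steps=2 * COARSE["n_steps"])
        plan2 = pl.solve_fixed_time(spec2, 0.7)
        assert plan1.cost_total == pytest.approx(plan2.cost_total, rel=5e-3)

    def test_matches_analytic_minimum_effort_on_linearized_plant(self):
        # 1-mm reach: the arm is effectively linear and the pure-effort
        # optimum has the controllability-Gramian closed form
        params = ArmParams()
        x0, target = pl.make_task([50.0, 100.0], 135.0, 0.001, params)
        spec = pl.OCPSpec(x0=x0, target=target, r=0.0, alpha=0.0,
                          params=params,
                          noise=NoiseParams.symmetric(0.0, 0.0),
                          n_controls=25, n_steps=100)
        plan = pl.solve_fixed_time(spec, 0.4)
        qf = arm.inverse_kinematics(target, params)
        analytic = min_effort_cost_linear(params, x0, qf, 0.4)
        assert plan.cost_total == pytest.approx(analytic, rel=1e-2)

    def test_free_time_interior_minimum_and_mesh_independence(
            self, free_plan_coarse, nw_spec_coarse):
        T_star = free_plan_coarse.T
        # bracketing fixed-time solves are not cheaper
        for T in (0.85 * T_star, 1.15 * T_star):
            other = pl.solve_fixed_time(nw_spec_coarse, T,
                                        u_guess=free_plan_coarse.u_nodes)
            assert other.cost_total >= free_plan_coarse.cost_total * (1 - 1e-6)
        spec_fine = make_nw_spec(n_controls=2 * COARSE["n_controls"] - 1,
                                 n_steps=2 * COARSE["n_steps"])
        plan_fine = pl.solve_free_time(spec_fine, T_guess=T_star)
        assert plan_fine.T == pytest.approx(T_star, rel=0.02)

    def test_duration_monotone_in_noise_magnitudes(self):
        # more constant noise -> variance accumulates faster with duration ->
        # faster movements; more signal-dependent noise penalizes large
        # commands -> slower movements
        T_by_sigma = []
        for sigma in (0.003, 0.005, 0.009):
            spec = make_nw_spec(noise=NoiseParams.symmetric(sigma, 0.01),
                                **COARSE)
            T_by_sigma.append(pl.solve_free_time(spec, T_guess=1.1).T)
        assert T_by_sigma[0] >= T_by_sigma[1] >= T_by_sigma[2]
        T_by_d = []
        for d in (0.005, 0.01, 0.02):
            spec = make_nw_spec(noise=NoiseParams.symmetric(0.005, d),
                                **COARSE)
            T_by_d.append(pl.solve_free_time(spec, T_guess=1.1).T)
        assert T_by_d[0] <= T_by_d[1] <= T_by_d[2]

    def test_sigma_zero_warns_no_finite_optimum(self):
        spec = make_nw_spec(noise=NoiseParams.symmetric(0.0, 0.01), **COARSE)
        with pytest.warns(UserWarning, match="sigma = 0"):
            try:
                pl.solve_free_time(spec, T_guess=0.5)
            except RuntimeError:
                pass  # non-convergence is acceptable: no interior optimum

    def test_fixed_time_rejects_nonpositive_duration(self, nw_spec_coarse):
        with pytest.raises(ValueError):
            pl.solve_fixed_time(nw_spec_coarse, -0.5)

    def test_scan_records_costs_and_continues_on_failure(self, nw_spec_coarse):
        df = pl.cost_vs_duration_scan(nw_spec_coarse, [0.5, 0.9])
        assert list(df["T"]) == [0.5, 0.9]
        assert df["converged"].all()
        assert (df["total"] >= df["variance"]).all()


class TestSpecValidation:
    def test_invalid_inputs(self):
        x0, target = pl.make_task([50, 100], 135.0, 0.074)
        with pytest.raises(ValueError):
            pl.OCPSpec(x0=x0[:4], target=target)
        with pytest.raises(ValueError):
            pl.OCPSpec(x0=x0, target=target, r=-1.0)
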