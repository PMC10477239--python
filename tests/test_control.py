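import numpy as np
import pytest
from scipy.optimize import brentq

from invasim.control import (
    ObjectiveParams,
    _forward_arrays,
    forward_backward_sweep,
    gradient_wrt_effort,
    objective,
    optimal_effort,
    solve_adjoint,
)
from invasim.grids import Grid
from invasim.invasion import ModelParams, StateField, diffusion_operator, simulate, total_population


def make_problem(n=10, h=20.0, dt=0.05, T=1.0, seed=0, **weights):
    rng = np.random.default_rng(seed)
    p = ModelParams(D=50.0, r=0.5, k=1.0, mu=1.0, tau=0.1)
    w = ObjectiveParams(**{**dict(alpha=1, beta=1, gamma=10, theta=10,
                                  delta=0.05, B=2, T=T), **weights})
    rho = Grid(values=rng.uniform(0.2, 1.0, (n, n)), cellsize=h)
    u0 = rng.uniform(0.0, 0.5, (n, n))
    N = int(round(T / dt))
    op = diffusion_operator(n, n, h, p.D, dt, "imex")
    return p, w, rho, u0, N, op, dt, h


class TestObjective:
    def test_zero_effort_leaves_damage_terms(self):
        p, w, rho, u0, N, op, dt, h = make_problem()
        Es = [np.zeros((10, 10)) for _ in range(N + 1)]
        us = _forward_arrays(u0, Es, rho.values, dt, p, op)
        J = objective(us, Es, w, dt, h)
        tw = np.full(N + 1, dt)
        tw[0] = tw[-1] = dt / 2
        expected = sum(
            tw[n] * np.exp(-w.delta * n * dt) * w.gamma * us[n].sum() * h**2
            for n in range(N + 1)
        ) + w.theta * np.exp(-w.delta * w.T) * us[-1].sum() * h**2
        assert J == pytest.approx(expected)

    def test_constant_effort_closed_form(self):
        # u = 0, delta = 0, unit area: J = (alpha c^2 + beta c^3/B^3) T
        w = ObjectiveParams(alpha=2.0, beta=3.0, gamma=1.0, theta=1.0,
                            delta=1e-12, B=2.0, T=1.0)
        c, N = 0.7, 20
        dt = w.T / N
        us = [np.zeros((1, 1)) for _ in range(N + 1)]
        Es = [np.full((1, 1), c) for _ in range(N + 1)]
        J = objective(us, Es, w, dt, cellsize=1.0)
        assert J == pytest.approx((2.0 * c**2 + 3.0 * c**3 / 8.0) * w.T, rel=1e-9)

    def test_effort_scaling_homogeneity(self):
        p, w0, rho, u0, N, op, dt, h = make_problem()
        rng = np.random.default_rng(3)
        Es = [rng.uniform(0, 1, (10, 10)) for _ in range(N + 1)]
        us = [np.zeros((10, 10)) for _ in range(N + 1)]
        wa = ObjectiveParams(alpha=1, beta=0, gamma=0, theta=0, delta=0.05, B=2, T=w0.T)
        wb = ObjectiveParams(alpha=0, beta=1, gamma=0, theta=0, delta=0.05, B=2, T=w0.T)
        Ja1 = objective(us, Es, wa, dt, h)
        Jb1 = objective(us, Es, wb, dt, h)
        E2 = [2 * E for E in Es]
        assert objective(us, E2, wa, dt, h) == pytest.approx(4 * Ja1)
        assert objective(us, E2, wb, dt, h) == pytest.approx(8 * Jb1)

    def test_mismatched_lengths_rejected(self):
        w = ObjectiveParams()
        with pytest.raises(ValueError, match="lengths"):
            objective([np.zeros((2, 2))] * 3, [np.zeros((2, 2))] * 2, w, 0.1, 1.0)


class TestAdjoint:
    def test_no_cost_gives_zero_adjoint(self):
        p, w, rho, u0, N, op, dt, h = make_problem(gamma=0.0, theta=0.0)
        Es = [np.zeros((10, 10)) for _ in range(N + 1)]
        us = _forward_arrays(u0, Es, rho.values, dt, p, op)
        lam = solve_adjoint(us, Es, rho, p, w, dt)
        assert max(np.abs(l).max() for l in lam) == 0.0

    def test_uniform_problem_reduces_to_scalar_recursion(self):
        """With u = 0, E = 0 and uniform rho the adjoint is spatially flat and
        equals the scalar backward recursion of -l' = r rho l + gamma e^{-dt}."""
        n, h, dt, T = 8, 20.0, 0.01, 1.0
        p = ModelParams(D=50.0, r=0.5)
        w = ObjectiveParams(gamma=3.0, theta=2.0, delta=0.1, T=T)
        rho = Grid(values=np.full((n, n), 0.6), cellsize=h)
        N = int(round(T / dt))
        Es = [np.zeros((n, n))] * (N + 1)
        us = [np.zeros((n, n))] * (N + 1)
        lam = solve_adjoint(us, Es, rho, p, w, dt)
        assert all(np.ptp(l) < 1e-12 for l in lam)  # spatially uniform
        # independent scalar integration of the same linear ODE
        a = p.r * 0.6
        lam_scalar = np.empty(N + 1)
        lam_scalar[N] = w.theta * np.exp(-w.delta * T) + (dt / 2) * w.gamma * np.exp(-w.delta * T)
        for k in range(N - 1, -1, -1):
            tw = dt if k > 0 else dt / 2
            growth = 1.0 + 0.5 * dt * (a + a * (1.0 + dt * a))  # Heun linearization
            lam_scalar[k] = growth * lam_scalar[k + 1] + tw * w.gamma * np.exp(-w.delta * k * dt)
        field_vals = np.array([l[0, 0] for l in lam])
        assert np.max(np.abs(field_vals - lam_scalar)) < 1e-6
        # consistency with the true ODE solution (scheme is O(dt) accurate)
        from scipy.integrate import solve_ivp

        sol = solve_ivp(lambda t, y: -(a * y + w.gamma * np.exp(-w.delta * t)),
                        (T, 0), [w.theta * np.exp(-w.delta * T)], rtol=1e-10, atol=1e-12)
        assert lam[0][0, 0] == pytest.approx(sol.y[0, -1], rel=5e-3)

    def test_gradient_matches_finite_differences(self):
        p, w, rho, u0, N, op, dt, h = make_problem(T=1.0)
        rng = np.random.default_rng(1)
        Es = [rng.uniform(0, 1, (10, 10)) for _ in range(N + 1)]
        us = _forward_arrays(u0, Es, rho.values, dt, p, op)
        lam = solve_adjoint(us, Es, rho, p, w, dt)
        grads = gradient_wrt_effort(us, Es, lam, rho, p, w, dt)

        def J_of(Elist):
            u = _forward_arrays(u0, Elist, rho.values, dt, p, op)
            return objective(u, Elist, w, dt, h)

        eps = 1e-5
        for _ in range(5):
            d = [rng.standard_normal((10, 10)) for _ in range(N + 1)]
            fd = (J_of([E + eps * di for E, di in zip(Es, d)])
                  - J_of([E - eps * di for E, di in zip(Es, d)])) / (2 * eps)
            ad = sum(float(np.sum(g * di)) for g, di in zip(grads, d))
            assert abs(fd - ad) / abs(fd) < 1e-3


class TestOptimalEffort:
    def test_no_marginal_benefit_means_no_effort(self):
        p, w = ModelParams(), ObjectiveParams()
        assert optimal_effort(-1.0, 0.5, 0.0, p, w) == 0.0
        assert optimal_effort(5.0, 0.0, 0.0, p, w) == 0.0

    def test_linear_case_beta_zero(self):
        p = ModelParams(mu=0.9, tau=0.2)
        w = ObjectiveParams(alpha=2.0, beta=0.0, delta=1e-9, B=1.0)
        lam, u = 3.0, 0.7
        expect = lam * p.mu * u / (2 * w.alpha * (1 + p.tau * p.mu * u))
        assert optimal_effort(lam, u, 0.0, p, w) == pytest.approx(expect, rel=1e-6)

    def test_quadratic_root_against_numeric_solver(self):
        p = ModelParams(mu=1.0, tau=0.0)
        w = ObjectiveParams(alpha=1.0, beta=1.0, delta=1e-12, B=1.0)
        lam, u = 5.0, 1.0  # c = 5: solve 3E^2 + 2E - 5 = 0 -> E = 1
        E = optimal_effort(lam, u, 0.0, p, w)
        assert E == pytest.approx(1.0, rel=1e-9)
        root = brentq(lambda e: 3 * e**2 + 2 * e - 5, 0, 10)
        assert E == pytest.approx(root, rel=1e-9)

    def test_unbounded_configuration_rejected(self):
        with pytest.raises(ValueError, match="unbounded"):
            optimal_effort(1.0, 1.0, 0.0, ModelParams(),
                           ObjectiveParams(alpha=0.0, beta=0.0))


class TestSweep:
    def test_no_damage_cost_means_no_control(self, small_scenario):
        p = ModelParams(D=50.0)
        w = ObjectiveParams(gamma=0.0, theta=0.0, T=2.0)
        pol = forward_backward_sweep(small_scenario["state0"].u, small_scenario["hsi"],
                                     p, w, dt=0.1)
        assert pol.iterations <= 2
        assert max(float(e.E.values.max()) for e in pol.E) == 0.0

    def test_sweep_beats_no_control(self, small_scenario):
        p = ModelParams(D=50.0)
        w = ObjectiveParams(T=5.0)
        pol = forward_backward_sweep(small_scenario["state0"].u, small_scenario["hsi"],
                                     p, w, dt=0.05, max_iter=40)
        J = np.asarray(pol.J_history)
        assert np.all(np.diff(J) <= 1e-9 * np.maximum(1.0, np.abs(J[:-1])))
        assert J[-1] < J[0]  # J(E*) < J(0): doing nothing is the first iterate
        un = simulate(small_scenario["state0"], None, 0.0, 5.0, 0.05,
                      small_scenario["hsi"], p)
        assert total_population(pol.u[-1]) < total_population(un[-1])
        assert all(np.all(e.E.values >= 0) for e in pol.E)

    def test_budget_penalty_caps_effort(self, small_scenario):
        p = ModelParams(D=50.0)
        max_E = {}
        for beta in (1.0, 10.0):
            w = ObjectiveParams(alpha=0.2, beta=beta, B=1.0, T=3.0)
            pol = forward_backward_sweep(small_scenario["state0"].u,
                                         small_scenario["hsi"], p, w, dt=0.1, max_iter=25)
            max_E[beta] = max(float(e.E.values.max()) for e in pol.E)
        assert max_E[10.0] <= max_E[1.0] + 1e-9

    def test_terminal_weight_shifts_effort_late(self, small_scenario):
        p = ModelParams(D=50.0)
        w = ObjectiveParams(alpha=1, beta=1, gamma=0.0, theta=100.0, T=5.0)
        pol = forward_backward_sweep(small_scenario["state0"].u, small_scenario["hsi"],
                                     p, w, dt=0.1, max_iter=25)
        tot = [float(e.E.values.sum()) for e in pol.E]
        half = len(tot) // 2
        assert sum(tot[half:]) >= 0.8 * sum(tot[:half])  # loose: not front-loaded

    def test_mask_confines_effort(self, small_scenario):
        p = ModelParams(D=50.0)
        w = ObjectiveParams(T=2.0)
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :] = True
        pol = forward_backward_sweep(small_scenario["state0"].u, small_scenario["hsi"],
                                     p, w, dt=0.1, max_iter=15, mask=mask)
        for e in pol.E:
            assert np.all(e.E.values[~mask] == 0.0)
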