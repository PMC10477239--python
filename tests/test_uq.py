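import itertools
from math import factorial

import numpy as np
import pytest

from invasim.invasion import ModelParams, initial_density, simulate
from invasim.hsi import kfold_scores, project_scores
from invasim.synthetic import ScenarioSpec, make_scenario
from invasim.uq import (
    basis_for_gaussians,
    fit_expansion,
    gauss_rule_from_moments,
    gaussian_moments,
    index_matrix,
    orthopoly_from_moments,
    propagate,
    smolyak_grid,
)


def brute_force_term_count(n_u, p):
    return sum(1 for idx in itertools.product(range(p + 1), repeat=n_u) if sum(idx) <= p)


class TestOrthopoly:
    def test_gaussian_moments_reproduce_hermite(self):
        table = orthopoly_from_moments(gaussian_moments(0, 1, 6), 2)
        # probabilists' Hermite, orthonormal: 1, x, (x^2 - 1)/sqrt(2)
        np.testing.assert_allclose(table[0], [1, 0, 0], atol=1e-6)
        np.testing.assert_allclose(table[1], [0, 1, 0], atol=1e-6)
        np.testing.assert_allclose(table[2], [-1 / np.sqrt(2), 0, 1 / np.sqrt(2)], atol=1e-6)

    def test_uniform_moments_reproduce_legendre(self):
        mom = [1 / (k + 1) if k % 2 == 0 else 0.0 for k in range(7)]
        table = orthopoly_from_moments(mom, 2)
        # orthonormal Legendre on [-1,1] w.r.t. the uniform density:
        # sqrt(3) x and sqrt(5)(3x^2-1)/2
        np.testing.assert_allclose(table[1], [0, np.sqrt(3), 0], atol=1e-6)
        np.testing.assert_allclose(table[2], [-np.sqrt(5) / 2, 0, 3 * np.sqrt(5) / 2], atol=1e-6)

    def test_orthonormality_for_skewed_distribution(self):
        # exponential(1): m_k = k!
        mom = [factorial(k) for k in range(7)]
        table = orthopoly_from_moments(mom, 3)
        assert table[0][0] == pytest.approx(1.0)
        # <psi_i psi_j> under the moment functional
        for i in range(4):
            for j in range(4):
                acc = sum(table[i][a] * table[j][b] * mom[a + b]
                          for a in range(4) for b in range(4))
                assert acc == pytest.approx(1.0 if i == j else 0.0, abs=1e-8)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            orthopoly_from_moments(gaussian_moments(0.5, 0.0, 6), 2)


class TestIndexMatrix:
    def test_four_input_degree_two_dimensions(self):
        assert index_matrix(4, 2).shape == (15, 4)

    def test_univariate_orders(self):
        np.testing.assert_array_equal(index_matrix(1, 3), [[0], [1], [2], [3]])

    @pytest.mark.parametrize("n_u,p", [(n, p) for n in range(1, 6) for p in range(5)])
    def test_term_count_matches_brute_force(self, n_u, p):
        I = index_matrix(n_u, p)
        assert I.shape[0] == brute_force_term_count(n_u, p)
        assert I.shape[0] == factorial(n_u + p) // (factorial(n_u) * factorial(p))
        assert np.all(I.sum(axis=1) <= p)
        assert len({tuple(r) for r in I}) == I.shape[0]
        np.testing.assert_array_equal(I[0], 0)


class TestGaussRule:
    def test_three_point_gauss_hermite(self):
        nodes, weights = gauss_rule_from_moments(gaussian_moments(2.0, 0.5, 6), 3)
        np.testing.assert_allclose(nodes, 2.0 + 0.5 * np.sqrt(3) * np.array([-1, 0, 1]), atol=1e-9)
        np.testing.assert_allclose(weights, [1 / 6, 2 / 3, 1 / 6], atol=1e-9)


class TestSmolyak:
    def test_nine_nodes_for_four_inputs(self):
        grid = smolyak_grid([gaussian_moments(0, 1, 6)] * 4, level=1)
        assert grid.n_nodes == 9

    def test_one_dimension_recovers_gauss_rule(self):
        grid = smolyak_grid([gaussian_moments(1.0, 0.2, 6)], level=1)
        assert grid.n_nodes == 3
        np.testing.assert_allclose(sorted(grid.weights), sorted([1 / 6, 2 / 3, 1 / 6]), atol=1e-9)

    def test_quadrature_normalization_and_degree2_exactness(self):
        means, sds = [0.5, 1.0, 0.2, 0.8], [0.1, 0.3, 0.05, 0.2]
        grid = smolyak_grid([gaussian_moments(m, s, 6) for m, s in zip(means, sds)])
        assert grid.weights.sum() == pytest.approx(1.0)
        assert grid.integrate(np.ones(grid.n_nodes)) == pytest.approx(1.0)
        # every total-degree-<=2 monomial integrates to its true moment
        for i in range(4):
            xi = grid.nodes[:, i]
            assert grid.integrate(xi) == pytest.approx(means[i], abs=1e-10)
            assert grid.integrate(xi**2) == pytest.approx(means[i] ** 2 + sds[i] ** 2, abs=1e-10)
            for j in range(i + 1, 4):
                assert grid.integrate(xi * grid.nodes[:, j]) == pytest.approx(
                    means[i] * means[j], abs=1e-10)


@pytest.fixture(scope="module")
def setup():
    grid = smolyak_grid([gaussian_moments(0, 1, 6)] * 2)
    basis = basis_for_gaussians([0, 0], [1, 1], p=2)
    return grid, basis


class TestFitExpansion:
    def test_constant_model(self, setup):
        grid, basis = setup
        exp = fit_expansion([np.full((4, 4), 3.25)] * grid.n_nodes, grid, basis)
        assert np.all(exp.mean == pytest.approx(3.25))
        assert np.abs(exp.coeffs[1:]).max() < 1e-10
        assert np.all(exp.sd < 1e-10)

    def test_single_mode_recovery(self, setup):
        grid, basis = setup
        outputs = [np.atleast_1d(basis.eval_univariate(1, 1, node[1])) for node in grid.nodes]
        exp = fit_expansion(outputs, grid, basis)
        k = next(i for i, row in enumerate(basis.index) if tuple(row) == (0, 1))
        assert exp.coeffs[k][0] == pytest.approx(1.0)
        rest = np.delete(exp.coeffs, k, axis=0)
        assert np.abs(rest).max() < 1e-10

    def test_degree_two_polynomial_mean_and_variance(self, setup):
        grid, basis = setup
        f = lambda x: 1.0 + 2.0 * x[0] + x[1] ** 2 - 0.5 * x[1]
        exp = fit_expansion([np.atleast_1d(f(n)) for n in grid.nodes], grid, basis)
        assert exp.mean[0] == pytest.approx(2.0, abs=1e-8)  # E f = 1 + E x2^2 = 2
        # Var = 4 Var(x1) + Var(x2^2 - x2/2) = 4 + (2 + 1/4)
        assert exp.variance[0] == pytest.approx(6.25, abs=1e-8)

    def test_node_count_mismatch_rejected(self, setup):
        grid, basis = setup
        with pytest.raises(ValueError, match="nodes"):
            fit_expansion([np.zeros(2)] * (grid.n_nodes - 1), grid, basis)


@pytest.fixture(scope="module")
def scenario():
    spec = ScenarioSpec(shape=(40, 40), n_classes=8, blob_scale=3.0,
                        presence_rate=0.08, seed=7)
    lu, presence = make_scenario(spec)
    scores = kfold_scores(lu, presence, k=5)
    uncertain = sorted(scores.mean, key=lambda c: -scores.mean[c])[:4]
    return lu, presence, scores.mean, uncertain


class TestPropagate:
    def test_zero_sd_equals_deterministic_run(self, scenario):
        lu, presence, scores, uncertain = scenario
        p = ModelParams(D=100.0)
        means, sds, exp = propagate(lu, presence, scores, uncertain,
                                    {c: 0.0 for c in uncertain}, p,
                                    t0=0.0, t1=1.0, dt=0.05, out_times=[1.0])
        assert exp is None
        hsi = project_scores(lu, scores)
        det = simulate(initial_density(presence, hsi), None, 0.0, 1.0, 0.05, hsi, p)[-1]
        assert np.abs(means[1.0].values - det.u.values).max() < 1e-10
        assert np.all(sds[1.0].values == 0.0)

    def test_initial_sd_confined_to_uncertain_presences(self, scenario):
        lu, presence, scores, uncertain = scenario
        p = ModelParams(D=100.0)
        sd_map = {c: 0.2 * scores[c] for c in uncertain}
        means, sds, _ = propagate(lu, presence, scores, uncertain, sd_map, p,
                                  t0=0.0, t1=1.0, dt=0.05, out_times=[0.0, 1.0])
        sd0 = sds[0.0].values
        uncertain_presence = (presence.values == 1) & np.isin(lu.values, uncertain)
        # certain cells carry only float rounding noise from the projection
        assert sd0[~uncertain_presence].max() < 1e-10
        assert sd0[uncertain_presence].max() > 0.0
        assert np.all(sds[1.0].values >= 0.0)

    def test_mean_within_node_envelope_at_t0(self, scenario):
        """At t = 0 the response is linear in each score, so the expansion
        mean must lie inside the per-node min/max envelope."""
        lu, presence, scores, uncertain = scenario
        p = ModelParams(D=100.0)
        sd_map = {c: 0.2 * scores[c] for c in uncertain}
        lo = dict(scores)
        hi = dict(scores)
        for c in uncertain:
            lo[c] = scores[c] - np.sqrt(3) * sd_map[c]
            hi[c] = scores[c] + np.sqrt(3) * sd_map[c]
        means, _, _ = propagate(lu, presence, scores, uncertain, sd_map, p,
                                t0=0.0, t1=1.0, dt=0.05, out_times=[0.0])
        u_lo = initial_density(presence, project_scores(lu, lo)).u.values
        u_hi = initial_density(presence, project_scores(lu, hi)).u.values
        m = means[0.0].values
        assert np.all(m >= u_lo - 1e-12)
        assert np.all(m <= u_hi + 1e-12)
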