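import numpy as np
import pytest

from grnkit import (
    ExpressionMatrix,
    bayesian_glasso,
    build_precision,
    glasso,
    glasso_sf,
    glasso_weighted,
    sample_expression,
    standardize,
)
from grnkit.likelihood import glasso_dual_gap, glasso_path, glasso_sf_path, mle_covariance

from conftest import chain_network, iid_normal


def make_star_precision(p=30, hub_degree=10, weight=0.28, seed=0):
    """Synthetic positive-definite star precision: gene 1 is the hub.

    Built directly (unit diagonal, equal hub-edge weights chosen for
    diagonal dominance) because the row-rescaling recipe used by the
    simulator cannot produce a positive-definite matrix for a degree-10
    star.
    """
    rng = np.random.default_rng(seed)
    omega = np.eye(p)
    for j in range(1, hub_degree + 1):
        s = rng.choice([-1.0, 1.0])
        omega[0, j] = omega[j, 0] = s * weight
    assert np.linalg.eigvalsh(omega).min() > 0
    return omega


def sample_precision(omega, n, seed):
    p = omega.shape[0]
    rng = np.random.default_rng(seed)
    vals = rng.multivariate_normal(np.zeros(p), np.linalg.inv(omega), size=n).T
    x = ExpressionMatrix(vals, [f"g{i + 1}" for i in range(p)], [f"s{i + 1}" for i in range(n)])
    return standardize(x)


class TestGlasso:
    def test_invalid_rho(self):
        with pytest.raises(ValueError, match="rho"):
            glasso(iid_normal(4, 50, 0), 0.0)

    def test_saturation_gives_empty_network(self):
        x = iid_normal(6, 80, 1)
        s = mle_covariance(x)
        off = np.abs(s - np.diag(np.diag(s)))
        w, omega = glasso(x, float(off.max()) * 1.001, return_precision=True)
        assert np.all(w.strengths == 0.0)
        assert np.count_nonzero(omega - np.diag(np.diag(omega))) == 0

    def test_small_rho_recovers_inverse_sample_covariance(self):
        x = iid_normal(5, 10_000, 2)
        _, omega = glasso(x, 1e-6, return_precision=True)
        target = np.linalg.inv(mle_covariance(x))
        assert np.abs(omega - target).max() < 1e-3

    def test_duality_gap_small_along_grid(self):
        x = iid_normal(6, 120, 3)
        s = mle_covariance(x)
        for rho in (0.3, 0.1, 0.03):
            _, omega = glasso(x, rho, return_precision=True)
            assert abs(glasso_dual_gap(s, omega, rho)) < 1e-6

    def test_subgradient_optimality(self):
        x = iid_normal(6, 120, 8)
        rho = 0.08
        _, omega = glasso(x, rho, return_precision=True)
        grad = mle_covariance(x) - np.linalg.inv(omega)
        iu = np.triu_indices(6, 1)
        for i, j in zip(*iu):
            if omega[i, j] != 0:
                assert abs(grad[i, j] + rho * np.sign(omega[i, j])) < 1e-5
            else:
                assert abs(grad[i, j]) <= rho + 1e-5

    def test_sample_order_invariance(self):
        x = iid_normal(5, 60, 4)
        perm = np.random.default_rng(0).permutation(60)
        xp = ExpressionMatrix(x.values[:, perm], list(x.gene_ids), [x.sample_ids[i] for i in perm])
        np.testing.assert_allclose(glasso(x, 0.1).strengths, glasso(xp, 0.1).strengths, atol=1e-12)


class TestGlassoWeighted:
    def test_uniform_penalty_matches_scalar_solver(self):
        # independent-route check: block-CD matrix solver vs scikit-learn
        x = iid_normal(8, 150, 5)
        rho = 0.1
        pen = np.full((8, 8), rho)
        np.fill_diagonal(pen, 0.0)
        _, om_mat = glasso_weighted(x, pen, return_precision=True)
        _, om_sk = glasso(x, rho, return_precision=True)
        assert np.abs(om_mat - om_sk).max() < 1e-4

    def test_invalid_penalty(self):
        x = iid_normal(4, 50, 6)
        with pytest.raises(ValueError, match="symmetric"):
            glasso_weighted(x, np.triu(np.full((4, 4), 0.1)))


class TestGlassoSF:
    def test_single_iteration_reduces_to_glasso(self):
        x = iid_normal(7, 100, 7)
        np.testing.assert_array_equal(
            glasso_sf(x, 0.1, reweight_iters=1).strengths, glasso(x, 0.1).strengths
        )

    def test_hub_edge_retention_vs_glasso(self):
        omega = make_star_precision()
        x = sample_precision(omega, 500, 9)
        hub_edges = {(0, j) for j in range(1, 11)}
        iu = np.triu_indices(30, 1)
        compared = 0
        for rho in (0.1, 0.12, 0.16):
            wg = glasso(x, rho)
            wsf = glasso_sf(x, rho)
            # matched total edge count: compare the top-k edges of each,
            # k being the sparser network's edge count
            k = min(
                int(np.count_nonzero(wg.strengths[iu])),
                int(np.count_nonzero(wsf.strengths[iu])),
            )
            if k == 0:
                continue
            compared += 1

            def hub_hits(w):
                vals = np.abs(w.strengths[iu])
                top = np.argsort(-vals)[:k]
                return sum((iu[0][t], iu[1][t]) in hub_edges for t in top)

            assert hub_hits(wsf) >= hub_hits(wg)
        assert compared >= 2

    def test_path_edge_counts_monotone(self):
        x = iid_normal(8, 100, 10)
        counts = glasso_sf_path(x, np.geomspace(0.5, 0.02, 10), reweight_iters=2).edge_counts()
        assert np.all(np.diff(counts) >= 0)


class TestBayesianGlasso:
    def test_parameter_validation(self):
        x = iid_normal(4, 50, 0)
        with pytest.raises(ValueError, match="lam"):
            bayesian_glasso(x, lam=0.0, iterations=10, burn_in=2)
        with pytest.raises(ValueError, match="burn_in"):
            bayesian_glasso(x, iterations=10, burn_in=10)

    def test_large_p_rejected_with_runtime_reason(self):
        rng = np.random.default_rng(0)
        x = ExpressionMatrix(
            rng.standard_normal((101, 10)), [f"g{i}" for i in range(101)], [f"s{i}" for i in range(10)]
        )
        with pytest.raises(ValueError, match="longer"):
            bayesian_glasso(standardize(x))

    def test_draws_positive_definite(self):
        x = iid_normal(5, 60, 1)
        _, trace = bayesian_glasso(x, iterations=200, burn_in=50, seed=3, return_trace=True)
        assert len(trace.samples) == (200 - 50 + 1) // 2
        for om in trace.samples[::10]:
            assert np.linalg.eigvalsh(om).min() > 0

    def test_deterministic_given_seed(self):
        x = iid_normal(5, 60, 2)
        a = bayesian_glasso(x, iterations=150, burn_in=30, seed=7)
        b = bayesian_glasso(x, iterations=150, burn_in=30, seed=7)
        np.testing.assert_array_equal(a.strengths, b.strengths)

    def test_edges_score_above_non_edges_on_chain(self):
        on_means, off_means = [], []
        for s in range(5):
            net = chain_network(5)
            ps = build_precision(net, seed=30 + s)
            x = standardize(sample_expression(ps, 1000, 0.0, seed=40 + s))
            w = bayesian_glasso(x, iterations=1500, burn_in=300, seed=s)
            a = np.abs(w.strengths)
            iu = np.triu_indices(5, 1)
            adj = ps.structure.adjacency()[iu]
            on_means.append(a[iu][adj].mean())
            off_means.append(a[iu][~adj].mean())
        assert np.mean(on_means) > np.mean(off_means)

    def test_two_chains_agree(self):
        x = iid_normal(5, 200, 5)
        a = bayesian_glasso(x, iterations=5000, burn_in=1000, seed=1)
        b = bayesian_glasso(x, iterations=5000, burn_in=1000, seed=2)
        assert np.abs(a.strengths - b.strengths).max() < 0.05
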