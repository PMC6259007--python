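"""Correlation inputs, graphical lasso, EBIC selection, and layout."""
import numpy as np
import pytest
from scipy import stats

import symnet as sn
from symnet.ggm import nearest_psd_correlation
from symnet.simulate import thresholds_for_moments


def _dataset(scores):
    scores = np.asarray(scores)
    return sn.SymptomDataset(
        items=tuple(f"V{i + 1}" for i in range(scores.shape[1])), scores=scores
    )


class TestCorrelation:
    def test_identical_and_negated_columns(self):
        x = np.array([0, 1, 2, 3, 4, 2, 1])
        ds = _dataset(np.column_stack([x, x, 4 - x]))
        R = sn.correlation(ds).values
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)

    def test_matches_direct_product_moment_formula(self):
        # independent oracle: raw-sum Pearson formula on a 5-case, 3-item table
        X = np.array(
            [[0, 2, 4], [1, 1, 3], [2, 3, 0], [3, 0, 2], [4, 4, 1]], dtype=float
        )
        n = 5
        expected = np.eye(3)
        for i in range(3):
            for j in range(3):
                sx, sy = X[:, i].sum(), X[:, j].sum()
                sxy = (X[:, i] * X[:, j]).sum()
                sxx, syy = (X[:, i] ** 2).sum(), (X[:, j] ** 2).sum()
                expected[i, j] = (n * sxy - sx * sy) / np.sqrt(
                    (n * sxx - sx**2) * (n * syy - sy**2)
                )
        R = sn.correlation(_dataset(X.astype(int))).values
        np.testing.assert_allclose(R, expected, atol=1e-12)

    def test_zero_variance_item_named_in_error(self):
        ds = _dataset(np.column_stack([[0, 1, 2, 3], [2, 2, 2, 2]]))
        with pytest.raises(sn.ValidationError, match="V2"):
            sn.correlation(ds)

    def test_psd_repair_is_idempotent(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed, repaired = nearest_psd_correlation(R)
        assert repaired
        again, repaired2 = nearest_psd_correlation(fixed)
        assert not repaired2
        np.testing.assert_allclose(again, fixed, atol=1e-10)
        assert np.linalg.eigvalsh(fixed).min() >= 0


class TestPolychoric:
    @staticmethod
    def _ordinal_pair(rho, n, seed):
        rng = np.random.default_rng(seed)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        cuts = stats.norm.ppf([0.2, 0.45, 0.7, 0.9])
        return np.searchsorted(cuts, z[:, 0]), np.searchsorted(cuts, z[:, 1])

    def test_independent_items_estimate_near_zero(self):
        x, y = self._ordinal_pair(0.0, 50_000, seed=11)
        assert abs(sn.polychoric(x, y)) < 0.02

    def test_recovers_latent_correlation(self):
        x, y = self._ordinal_pair(0.5, 50_000, seed=12)
        assert sn.polychoric(x, y) == pytest.approx(0.50, abs=0.02)

    def test_perfect_concordance_hits_solver_bound(self):
        x, _ = self._ordinal_pair(0.3, 2_000, seed=13)
        assert sn.polychoric(x, x) >= 0.99

    def test_single_category_rejected(self):
        with pytest.raises(sn.ValidationError):
            sn.polychoric(np.zeros(100, dtype=int), np.arange(100) % 5)


class TestGlasso:
    @staticmethod
    def _random_corr(p, seed, n=300):
        A = np.random.default_rng(seed).normal(size=(n, p))
        return np.corrcoef(A, rowvar=False)

    def test_saturating_penalty_gives_diagonal_precision(self):
        R = self._random_corr(5, seed=1)
        lam = np.abs(R - np.eye(5)).max()
        K = sn.glasso(R, lam * 1.0001)
        off = K - np.diag(np.diag(K))
        assert np.all(off == 0)

    def test_unpenalized_solution_equals_inverse(self):
        R = self._random_corr(6, seed=2)
        K = sn.glasso(R, 0.0)
        np.testing.assert_allclose(K, np.linalg.inv(R), atol=1e-6)

    def test_matches_independent_solver_on_chain_graph(self):
        # oracle: sklearn's graphical lasso run to tight tolerance
        from sklearn.covariance import graphical_lasso

        K0 = np.eye(4)
        for i in range(3):
            K0[i, i + 1] = K0[i + 1, i] = -0.4
        S = np.linalg.inv(K0)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        _, prec = graphical_lasso(S, alpha=0.05, tol=1e-12, max_iter=2000)
        K = sn.glasso(S, 0.05)
        np.testing.assert_allclose(K, prec, atol=1e-4)

    def test_negative_penalty_rejected(self):
        with pytest.raises(sn.ValidationError):
            sn.glasso(np.eye(3), -0.1)


class TestPrecisionToPartial:
    def test_diagonal_precision_gives_empty_network(self):
        net = sn.precision_to_partial(np.diag([1.0, 2.0, 3.0]))
        assert np.all(net.weights == 0)

    def test_two_by_two_closed_form(self):
        K = np.array([[2.0, -1.0], [-1.0, 2.0]])
        net = sn.precision_to_partial(K)
        assert net.weights[0, 1] == pytest.approx(0.5)
        # agreement with the covariance-inversion route
        S = np.linalg.inv(K)
        r = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
        assert net.weights[0, 1] == pytest.approx(r)

    def test_output_symmetric_and_bounded(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(8, 8))
        K = A @ A.T + 8 * np.eye(8)
        net = sn.precision_to_partial(K)
        assert np.allclose(net.weights, net.weights.T)
        assert np.abs(net.weights).max() <= 1.0

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(sn.ValidationError):
            sn.precision_to_partial(np.array([[1.0, 0.0], [0.0, -2.0]]))


class TestEbic:
    def test_no_edges_reduces_to_deviance(self):
        assert sn.ebic(-50.0, 0, 100, 17, 0.5) == pytest.approx(100.0)

    def test_gamma_zero_is_bic(self):
        ll, E, n, p = -80.0, 7, 200, 10
        assert sn.ebic(ll, E, n, p, 0.0) == pytest.approx(-2 * ll + E * np.log(n))

    def test_direct_arithmetic_example(self):
        val = sn.ebic(-100.0, 5, 100, 17, 0.5)
        assert val == pytest.approx(200 + 5 * np.log(100) + 10 * np.log(17))


class TestEstimateNetwork:
    @staticmethod
    def _chain6(n, seed, rho=0.3):
        P = np.zeros((6, 6))
        for i in range(5):
            P[i, i + 1] = P[i + 1, i] = rho
        thr = np.tile(thresholds_for_moments(2.0, 1.3), (6, 1))
        spec = sn.ScenarioSpec(
            items=tuple("ABCDEF"), partials=P, thresholds=thr, n=n, seed=seed
        )
        return spec, sn.sample_ordinal(spec)

    def test_recovers_sparse_chain_structure(self):
        spec, data = self._chain6(5000, seed=21)
        fit = sn.estimate_network(data)
        w = fit.network.weights
        true = spec.partials != 0
        assert np.all(w[true] != 0), "every true edge recovered"
        off = ~np.eye(6, dtype=bool)
        true_zeros = off & ~true
        frac_zero = np.mean(w[true_zeros] == 0)
        assert frac_zero >= 0.8

    def test_independent_items_give_empty_network(self):
        p = 6
        thr = np.tile(thresholds_for_moments(2.0, 1.3), (p, 1))
        spec = sn.ScenarioSpec(
            items=tuple("ABCDEF"), partials=np.zeros((p, p)), thresholds=thr,
            n=5000, seed=22,
        )
        fit = sn.estimate_network(sn.sample_ordinal(spec))
        assert np.all(fit.network.weights == 0)

    def test_estimates_converge_to_generator_partials(self):
        spec, data = self._chain6(20_000, seed=23)
        fit = sn.estimate_network(data)
        err = np.abs(fit.network.weights - spec.partials).max()
        assert err <= 0.05

    def test_deterministic_given_data(self):
        _, data = self._chain6(800, seed=24)
        f1 = sn.estimate_network(data)
        f2 = sn.estimate_network(data)
        np.testing.assert_array_equal(f1.network.weights, f2.network.weights)
        assert f1.lambda_selected == f2.lambda_selected

    def test_edge_count_grows_as_penalty_shrinks(self, clinical_5000):
        # lasso paths are only near-monotone; allow small local dips
        _, data = clinical_5000
        fit = sn.estimate_network(data)
        E = fit.ebic_path[:, 2]
        assert np.all(np.diff(E) >= -3)
        assert E[0] <= E[-1]

    def test_selected_lambda_minimizes_ebic_on_path(self, clinical_5000):
        _, data = clinical_5000
        fit = sn.estimate_network(data)
        path = fit.ebic_path
        assert path[path[:, 0] == fit.lambda_selected, 3][0] == path[:, 3].min()


class TestMeanEdgeWeight:
    def test_empty_network_is_zero(self):
        net = sn.Network(labels=("A", "B", "C"), weights=np.zeros((3, 3)))
        assert sn.mean_edge_weight(net) == 0.0

    def test_hand_summed_average_over_all_pairs(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.3
        w[0, 2] = w[2, 0] = 0.1
        w[1, 2] = w[2, 1] = -0.2
        net = sn.Network(labels=("A", "B", "C"), weights=w)
        assert sn.mean_edge_weight(net) == pytest.approx(0.2 / 3)
        assert sn.mean_edge_weight(net, include_zeros=False) == pytest.approx(0.2 / 3)

    def test_scaling_linearity(self):
        from .conftest import random_network

        net = random_network(6, seed=9)
        scaled = sn.Network(labels=net.labels, weights=0.5 * net.weights)
        assert sn.mean_edge_weight(scaled) == pytest.approx(
            0.5 * sn.mean_edge_weight(net)
        )


class TestLayout:
    def test_fixed_seed_reproducible(self):
        from .conftest import random_network

        net = random_network(7, seed=10)
        a = sn.layout_fruchterman_reingold(net, seed=5)
        b = sn.layout_fruchterman_reingold(net, seed=5)
        for lab in net.labels:
            np.testing.assert_array_equal(a[lab], b[lab])

    def test_single_node_at_origin(self):
        net = sn.Network(labels=("solo",), weights=np.zeros((1, 1)))
        np.testing.assert_array_equal(
            sn.layout_fruchterman_reingold(net, seed=0)["solo"], np.zeros(2)
        )

    def test_disconnected_nodes_get_distinct_finite_coordinates(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        net = sn.Network(labels=tuple("ABCD"), weights=w)
        pos = sn.layout_fruchterman_reingold(net, seed=1)
        coords = np.array([pos[lab] for lab in net.labels])
        assert np.all(np.isfinite(coords))
        assert len({tuple(c) for c in np.round(coords, 9)}) == 4
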