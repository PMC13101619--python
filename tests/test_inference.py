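"""Network inference: correlation, graphical lasso, partials, thresholding.

The graphical lasso is checked through three independent routes: closed
forms in the unpenalized and fully-shrunk limits, a dense numerical maximizer
of the penalized log-likelihood, and scikit-learn's implementation (for the
off-diagonal-penalty convention it uses).
"""

import numpy as np
import pandas as pd
import pytest

from carenet.errors import NotPositiveDefiniteError, ZeroVarianceError
from carenet.inference import (
    SUPPORT_FLOOR,
    fit_pipeline,
    graphical_lasso,
    partial_correlations,
    pearson_correlation,
    threshold_network,
)
from carenet.preprocess import CaseActivityMatrix

from .oracles import dense_glasso_oracle


def _matrix(arr, labels=None):
    arr = np.asarray(arr, dtype=float)
    labels = labels or [f"a{j}" for j in range(arr.shape[1])]
    return CaseActivityMatrix(
        data=pd.DataFrame(arr, columns=labels, index=[f"c{i}" for i in range(arr.shape[0])])
    )


def _random_correlation(rng, p, strength=0.3):
    X = rng.standard_normal((20 * p, p))
    X += strength * X @ rng.standard_normal((p, p))
    return np.corrcoef(X, rowvar=False)


class TestPearsonCorrelation:
    def test_duplicate_column_has_correlation_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        m = _matrix(np.column_stack([x, x, rng.normal(size=10)]))
        R = pearson_correlation(m)
        assert R.iloc[0, 1] == pytest.approx(1.0)

    def test_negative_affine_column(self):
        x = np.arange(8.0)
        m = _matrix(np.column_stack([x, -2 * x + 7]))
        R = pearson_correlation(m)
        assert R.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_hand_formula_on_toy_matrix(self):
        """5-case, 3-activity toy vs the sum-of-products formula."""
        arr = np.array(
            [[2, 7, 4], [5, 1, 0], [9, 3, 8], [4, 4, 2], [6, 2, 6]], dtype=float
        )

        def hand_r(x, y):
            n = len(x)
            sx, sy = x.sum(), y.sum()
            num = n * (x * y).sum() - sx * sy
            den = np.sqrt(n * (x**2).sum() - sx**2) * np.sqrt(n * (y**2).sum() - sy**2)
            return num / den

        R = pearson_correlation(_matrix(arr))
        for i in range(3):
            for j in range(3):
                assert R.iloc[i, j] == pytest.approx(hand_r(arr[:, i], arr[:, j]))

    def test_zero_variance_column_errors_with_name(self):
        m = _matrix(np.column_stack([np.arange(5.0), np.full(5, 3.0)]), ["ok", "flat"])
        with pytest.raises(ZeroVarianceError, match="flat"):
            pearson_correlation(m)

    def test_requires_three_cases(self):
        with pytest.raises(ValueError):
            pearson_correlation(_matrix(np.array([[1.0, 2.0], [3.0, 4.0]])))


class TestGraphicalLasso:
    def test_unpenalized_limit_is_matrix_inverse(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        fit = graphical_lasso(R, 0.0)
        expected = np.array([[4 / 3, -2 / 3], [-2 / 3, 4 / 3]])
        np.testing.assert_allclose(fit.theta, expected, atol=1e-6)

    def test_unpenalized_limit_random(self):
        rng = np.random.default_rng(1)
        R = _random_correlation(rng, 6)
        fit = graphical_lasso(R, 0.0)
        np.testing.assert_allclose(fit.theta, np.linalg.inv(R), atol=1e-6)

    def test_full_shrinkage_gives_diagonal_solution(self):
        rng = np.random.default_rng(2)
        R = _random_correlation(rng, 5)
        lam = np.abs(R - np.eye(5)).max() + 0.01
        fit = graphical_lasso(R, lam)
        off = fit.theta[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() == 0.0
        np.testing.assert_allclose(np.diag(fit.theta), 1.0 / (1.0 + lam), atol=1e-8)

    @pytest.mark.parametrize("penalize_diagonal", [True, False])
    def test_matches_dense_numerical_maximizer(self, penalize_diagonal):
        R = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.0], [0.3, 0.0, 1.0]])
        fit = graphical_lasso(R, 0.05, penalize_diagonal=penalize_diagonal)
        oracle = dense_glasso_oracle(R, 0.05, penalize_diagonal=penalize_diagonal)
        np.testing.assert_allclose(fit.theta, oracle, atol=1e-3)

    def test_matches_dense_maximizer_4x4(self):
        rng = np.random.default_rng(3)
        R = _random_correlation(rng, 4)
        fit = graphical_lasso(R, 0.1)
        oracle = dense_glasso_oracle(R, 0.1)
        np.testing.assert_allclose(fit.theta, oracle, atol=1e-3)

    @pytest.mark.parametrize("p,lam,seed", [(5, 0.05, 0), (10, 0.1, 1), (15, 0.02, 2),
                                            (8, 0.3, 3), (12, 0.05, 4)])
    def test_kkt_residual_small_on_every_fit(self, p, lam, seed):
        R = _random_correlation(np.random.default_rng(seed), p)
        fit = graphical_lasso(R, lam)
        assert fit.converged
        assert fit.kkt_residual <= 1e-4
        assert np.linalg.eigvalsh(fit.theta).min() > 0

    def test_cross_check_against_sklearn(self):
        from sklearn.covariance import graphical_lasso as sk_glasso

        rng = np.random.default_rng(4)
        R = _random_correlation(rng, 10)
        fit = graphical_lasso(R, 0.1, penalize_diagonal=False, kkt_tol=1e-6)
        _, prec = sk_glasso(R, alpha=0.1, tol=1e-10, max_iter=2000)
        np.testing.assert_allclose(fit.theta, prec, atol=5e-4)

    def test_edge_count_nonincreasing_in_lambda(self):
        rng = np.random.default_rng(5)
        R = _random_correlation(rng, 8)
        counts = []
        for lam in (0.01, 0.05, 0.1, 0.2, 0.4):
            fit = graphical_lasso(R, lam)
            P = partial_correlations(fit.theta)
            counts.append(int((np.abs(P[~np.eye(8, dtype=bool)]) > SUPPORT_FLOOR).sum()))
        assert counts == sorted(counts, reverse=True)

    def test_rejects_indefinite_input(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(R).min() < -1e-8
        with pytest.raises(NotPositiveDefiniteError):
            graphical_lasso(R, 0.05)


class TestPartialCorrelations:
    def test_diagonal_precision_gives_zero_partials(self):
        P = partial_correlations(np.diag([2.0, 3.0, 4.0]))
        assert np.allclose(P - np.eye(3), 0.0)

    def test_closed_form_two_variable(self):
        theta = np.array([[4 / 3, -2 / 3], [-2 / 3, 4 / 3]])
        P = partial_correlations(theta)
        assert P[0, 1] == pytest.approx(0.5)

    def test_two_variable_partial_equals_pearson_at_lam_zero(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.standard_normal((50, 2)) @ np.array([[1.0, 0.6], [0.0, 0.8]]))
        R = pearson_correlation(m)
        fit = graphical_lasso(R.to_numpy(), 0.0)
        P = partial_correlations(fit.theta)
        assert P[0, 1] == pytest.approx(R.iloc[0, 1], abs=1e-6)

    def test_matches_regression_residual_oracle(self):
        """Partial correlation == correlation of regression residuals."""
        rng = np.random.default_rng(7)
        A = rng.standard_normal((4, 4))
        theta = A @ A.T + 4 * np.eye(4)
        P = partial_correlations(theta)
        sigma = np.linalg.inv(theta)
        X = rng.multivariate_normal(np.zeros(4), sigma, size=400_000)
        for i, j in [(0, 1), (0, 3), (1, 2), (2, 3)]:
            others = [k for k in range(4) if k not in (i, j)]
            Z = np.column_stack([X[:, others], np.ones(len(X))])
            ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
            rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
            r = np.corrcoef(ri, rj)[0, 1]
            assert P[i, j] == pytest.approx(r, abs=0.02)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(NotPositiveDefiniteError):
            partial_correlations(np.array([[1.0, 0.0], [0.0, -1.0]]))


class TestThresholdNetwork:
    def test_threshold_is_inclusive(self):
        P = np.eye(2)
        P[0, 1] = P[1, 0] = 0.15
        net = threshold_network(P, 0.15, ["a", "b"])
        assert net.n_edges == 1
        assert net.edge_weights()[frozenset(("a", "b"))] == pytest.approx(0.15)

    def test_just_below_threshold_dropped(self):
        P = np.eye(2)
        P[0, 1] = P[1, 0] = -0.149
        net = threshold_network(P, 0.15, ["a", "b"])
        assert net.n_edges == 0 and net.removed_nodes == ["a", "b"]

    def test_tau_zero_keeps_exactly_supported_edges(self):
        P = np.eye(4)
        P[0, 1] = P[1, 0] = 0.3
        P[2, 3] = P[3, 2] = -0.02
        net = threshold_network(P, 0.0)
        assert net.n_edges == 2

    def test_edge_count_nonincreasing_in_tau(self):
        rng = np.random.default_rng(8)
        fit = graphical_lasso(_random_correlation(rng, 10), 0.02)
        P = partial_correlations(fit.theta)
        counts = [threshold_network(P, t).n_edges for t in (0.0, 0.05, 0.1, 0.2, 0.5)]
        assert counts == sorted(counts, reverse=True)

    def test_isolated_nodes_removed_and_logged(self):
        P = np.eye(3)
        P[0, 1] = P[1, 0] = 0.5
        net = threshold_network(P, 0.15, ["a", "b", "c"])
        assert net.nodes == ["a", "b"] and net.removed_nodes == ["c"]
        assert all(d >= 1 for _, d in net.graph.degree())


class TestFitPipeline:
    def test_planted_blocks_recovered_without_cross_edges(self):
        from carenet.synthetic import benchmark_recovery_spec, build_model, sample_case_totals

        spec = benchmark_recovery_spec(seed=1)
        gt = build_model(spec)
        m = sample_case_totals(gt, spec)
        _, net = fit_pipeline(m, lam=0.05, tau=0.15)
        blocks = gt.block_membership
        for pair in net.edge_weights():
            a, b = sorted(pair)
            assert blocks[a] == blocks[b] != -1, "cross-block edge estimated"
        strong = {e for e, w in gt.true_edges.items() if abs(w) >= 0.3}
        recovered = set(net.edge_weights())
        assert len(strong & recovered) / len(strong) >= 0.8

    def test_independent_columns_give_near_empty_network(self):
        rng = np.random.default_rng(9)
        m = _matrix(rng.standard_normal((5000, 12)))
        _, net = fit_pipeline(m, lam=0.05, tau=0.15)
        assert net.n_edges <= 0.01 * (12 * 11 / 2)

    def test_single_planted_pair_gives_exactly_one_edge(self):
        rng = np.random.default_rng(10)
        z = rng.standard_normal((4000, 6))
        z[:, 1] = 0.7 * z[:, 0] + np.sqrt(1 - 0.49) * z[:, 1]
        m = _matrix(z)
        _, net = fit_pipeline(m, lam=0.05, tau=0.15)
        assert set(net.edge_weights()) == {frozenset(("a0", "a1"))}

    def test_intermediates_are_retained_and_consistent(self):
        rng = np.random.default_rng(11)
        m = _matrix(rng.standard_normal((200, 5)))
        model, net = fit_pipeline(m, lam=0.1, tau=0.1)
        assert list(model.R.columns) == model.labels
        P = model.partial.to_numpy()
        np.testing.assert_allclose(np.diag(P), 1.0)
        np.testing.assert_allclose(P, P.T, atol=1e-12)
        assert model.kkt_residual <= 1e-4
        theta = model.theta.to_numpy()
        expected = -theta / np.sqrt(np.outer(np.diag(theta), np.diag(theta)))
        np.testing.assert_allclose(P[~np.eye(5, dtype=bool)],
                                   expected[~np.eye(5, dtype=bool)], atol=1e-12)
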