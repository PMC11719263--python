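"""Correlation input, glasso path, EBIC selection, partial-correlation output."""

import numpy as np
import pandas as pd
import pytest

from bridgenet import (
    GGMConfig,
    SurveyMatrix,
    correlation_matrix,
    ebic_score,
    estimate_network,
    generate_true_network,
    lambda_grid,
    penalised_precision,
    sample_likert,
    to_partial_correlations,
)
from bridgenet.ggm import CorrelationEstimate


def _random_pd_precision(p, rng):
    A = rng.normal(size=(p, p))
    K = A @ A.T + p * np.eye(p)
    return K


def partial_corr_oracle(K):
    """Regression-residual partial correlations from the covariance inv(K)."""
    p = K.shape[0]
    sigma = np.linalg.inv(K)
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            if others:
                s_oo = sigma[np.ix_(others, others)]
                s_io = sigma[np.ix_([i, j], others)]
                cond = sigma[np.ix_([i, j], [i, j])] - s_io @ np.linalg.solve(s_oo, s_io.T)
            else:
                cond = sigma[np.ix_([i, j], [i, j])]
            W[i, j] = W[j, i] = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
    return W


class TestCorrelationMatrix:
    def test_zero_variance_item_named(self):
        m = SurveyMatrix(pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 2, 2]}))
        with pytest.raises(ValueError, match="b"):
            correlation_matrix(m)

    def test_minimal_input(self):
        m = SurveyMatrix(pd.DataFrame({"a": [1.0, 2, 3], "b": [3.0, 1, 2]}))
        S = correlation_matrix(m)
        assert S.matrix.shape == (2, 2)
        assert np.all(np.diag(S.matrix) == 1.0)

    def test_listwise_deletion(self):
        m = SurveyMatrix(
            pd.DataFrame({"a": [1.0, 2, 3, np.nan], "b": [3.0, 1, 2, 5], "c": [2.0, 3, 1, 4]})
        )
        S = correlation_matrix(m)
        assert S.n_effective == 3

    def test_independence_correlations_small(self):
        t = generate_true_network(5, 4, 0.0, 0, seed=0)
        m = sample_likert(t, n=20000, seed=1)
        S = correlation_matrix(m)
        off = S.matrix - np.eye(S.p)
        assert np.abs(off).max() < 0.05

    def test_duplicate_columns_report_unit_correlation(self):
        m = SurveyMatrix(
            pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [1.0, 2, 3, 4, 5], "c": [2.0, 1, 4, 3, 5]})
        )
        S = correlation_matrix(m)
        assert S.matrix[0, 1] == pytest.approx(1.0)


class TestLambdaGrid:
    def test_endpoints(self):
        S = CorrelationEstimate(
            matrix=np.array([[1.0, 0.8], [0.8, 1.0]]), n_effective=100
        )
        grid = lambda_grid(S, GGMConfig(n_lambda=2, lambda_min_ratio=0.01))
        assert grid[0] == pytest.approx(0.8)
        assert grid[-1] == pytest.approx(0.008)

    def test_strictly_decreasing_with_requested_length(self):
        S = CorrelationEstimate(matrix=np.array([[1.0, 0.5], [0.5, 1.0]]), n_effective=50)
        grid = lambda_grid(S, GGMConfig(n_lambda=25))
        assert len(grid) == 25
        assert np.all(np.diff(grid) < 0)

    def test_identity_degenerates_with_warning(self):
        S = CorrelationEstimate(matrix=np.eye(3), n_effective=50)
        with pytest.warns(UserWarning):
            grid = lambda_grid(S, GGMConfig())
        assert list(grid) == [0.0]


class TestPenalisedPrecision:
    def test_large_penalty_gives_diagonal(self):
        rng = np.random.default_rng(0)
        t = generate_true_network(4, 3, 0.3, 2, seed=2)
        m = sample_likert(t, n=500, seed=3)
        S = correlation_matrix(m)
        lam = np.abs(S.matrix - np.eye(S.p)).max() * 1.01
        K = penalised_precision(S, lam)
        off = K - np.diag(np.diag(K))
        assert np.abs(off).max() < 1e-6

    def test_zero_penalty_is_inverse(self):
        S = CorrelationEstimate(
            matrix=np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]]),
            n_effective=100,
        )
        K = penalised_precision(S, 0.0)
        assert np.allclose(K, np.linalg.inv(S.matrix), atol=1e-6)

    def test_kkt_conditions_on_nonzeros(self):
        """Stationarity: -K^-1 + S + lam*sign(K) ~ 0 on active off-diagonals."""
        t = generate_true_network(5, 4, 0.3, 2, seed=4)
        m = sample_likert(t, n=1000, seed=5)
        cfg = GGMConfig()
        S = correlation_matrix(m)
        lam = 0.1
        K = penalised_precision(S, lam, cfg)
        resid = -np.linalg.inv(K) + S.matrix + lam * np.sign(K)
        np.fill_diagonal(resid, 0.0)
        active = np.abs(K - np.diag(np.diag(K))) > 1e-8
        assert np.abs(resid[active]).max() < 10 * cfg.glasso_tol

    def test_negative_penalty_rejected(self):
        S = CorrelationEstimate(matrix=np.eye(2), n_effective=10)
        with pytest.raises(ValueError):
            penalised_precision(S, -0.1)


class TestToPartialCorrelations:
    def test_closed_form_two_by_two(self):
        W = to_partial_correlations(np.array([[2.0, -1.0], [-1.0, 2.0]]))
        assert W[0, 1] == pytest.approx(0.5)
        assert W[0, 0] == 0.0

    def test_diagonal_precision_gives_zero_weights(self):
        W = to_partial_correlations(np.diag([1.0, 2.0, 3.0]))
        assert np.all(W == 0)

    def test_matches_regression_residual_oracle(self):
        rng = np.random.default_rng(7)
        for p in (3, 4, 5):
            K = _random_pd_precision(p, rng)
            W = to_partial_correlations(K)
            assert np.abs(W - partial_corr_oracle(K)).max() < 1e-8

    def test_non_positive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            to_partial_correlations(np.array([[0.0, 1.0], [1.0, 1.0]]))


class TestEbicScore:
    def test_gamma_zero_is_bic(self):
        S = CorrelationEstimate(
            matrix=np.array([[1.0, 0.5], [0.5, 1.0]]), n_effective=100
        )
        K = np.array([[1.5, -0.5], [-0.5, 1.5]])
        bic = ebic_score(K, S, 100, gamma=0.0)
        sign, logdet = np.linalg.slogdet(K)
        L = 50 * (logdet - np.trace(S.matrix @ K) + 2)
        assert bic == pytest.approx(-2 * L + 1 * np.log(100))

    def test_diagonal_on_identity_is_zero(self):
        S = CorrelationEstimate(matrix=np.eye(2), n_effective=100)
        assert ebic_score(np.eye(2), S, 100) == pytest.approx(0.0)

    def test_edge_penalty_increment(self):
        n, p, gamma = 100, 5, 0.5
        S = CorrelationEstimate(matrix=np.eye(p), n_effective=n)
        K0 = np.eye(p)
        K1 = K0.copy()
        K1[0, 1] = K1[1, 0] = 1e-6  # structurally present, numerically negligible
        delta = ebic_score(K1, S, n, gamma) - ebic_score(K0, S, n, gamma)
        assert delta == pytest.approx(np.log(n) + 4 * gamma * np.log(p), abs=1e-3)

    def test_non_pd_rejected(self):
        S = CorrelationEstimate(matrix=np.eye(2), n_effective=10)
        with pytest.raises(ValueError):
            ebic_score(np.array([[1.0, 2.0], [2.0, 1.0]]), S, 10)


class TestEstimateNetwork:
    def test_independence_recovers_empty_graph(self):
        t = generate_true_network(5, 4, 0.0, 0, seed=0)
        m = sample_likert(t, n=1000, seed=6)
        net = estimate_network(m, GGMConfig(n_lambda=30))
        assert net.nonzero_edges == 0

    def test_single_strong_edge_recovered(self):
        t = generate_true_network(3, 2, 0.0, 0, seed=0, extra_edges=[("L1", "L2", 0.6)])
        m = sample_likert(t, n=1000, seed=7)
        net = estimate_network(m, GGMConfig(n_lambda=30))
        w = net.to_frame().loc["L1", "L2"]
        assert abs(w) > 0.3
        assert net.nonzero_edges >= 1

    def test_total_edges_census(self):
        t = generate_true_network(15, 0, 0.15, 0, seed=1)
        m = sample_likert(t, n=300, seed=8)
        net = estimate_network(m, GGMConfig(n_lambda=20))
        assert net.total_edges == 105

    def test_path_endpoints(self):
        """Largest grid penalty empties the graph; smallest approaches saturation."""
        t = generate_true_network(4, 3, 0.4, 2, seed=9)
        m = sample_likert(t, n=800, seed=10)
        S = correlation_matrix(m)
        cfg = GGMConfig(n_lambda=10)
        grid = lambda_grid(S, cfg)
        K_sparse = penalised_precision(S, float(grid[0]) * 1.0001, cfg)
        off = K_sparse - np.diag(np.diag(K_sparse))
        assert np.abs(off).max() < 1e-6
        K_dense = penalised_precision(S, 0.0, cfg)
        i, j = np.triu_indices(S.p, k=1)
        assert (np.abs(K_dense[i, j]) > 1e-8).mean() > 0.9

    def test_deterministic(self):
        t = generate_true_network(4, 3, 0.3, 1, seed=11)
        m = sample_likert(t, n=400, seed=12)
        a = estimate_network(m, GGMConfig(n_lambda=15))
        b = estimate_network(m, GGMConfig(n_lambda=15))
        assert np.array_equal(a.weights, b.weights)
        assert a.lambda_selected == b.lambda_selected
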