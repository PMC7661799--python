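"""Graphical lasso, BIC penalty selection and partial-correlation conversion."""

import numpy as np
import pytest

from netpsych.datagen import GroupSpec, MeasureTable, VariableSpec, generate_group_sample
from netpsych.estimation import (
    PrecisionEstimate,
    bic_score,
    estimate_network,
    graphical_lasso,
    kkt_violation,
    precision_to_partial,
    select_penalty,
)


def _random_corr(rng, p, strength=1.0):
    a = rng.standard_normal((p, 3 * p)) * strength
    s = a @ a.T / (3 * p)
    d = np.sqrt(np.diag(s))
    s = s / np.outer(d, d)
    return s


S2 = np.array([[1.0, 0.5], [0.5, 1.0]])


class TestGraphicalLasso:
    def test_identity_input_returns_identity(self):
        est = graphical_lasso(np.eye(4), lam=0.2)
        assert np.allclose(est.precision, np.eye(4), atol=1e-8)

    def test_zero_penalty_equals_exact_inverse(self):
        est = graphical_lasso(S2, lam=0.0)
        expected = np.array([[4 / 3, -2 / 3], [-2 / 3, 4 / 3]])
        assert np.allclose(est.precision, expected, atol=1e-10)

    def test_penalty_at_least_correlation_kills_edge(self):
        for lam in (0.5, 0.6, 1.0):
            est = graphical_lasso(S2, lam=lam)
            assert est.precision[0, 1] == 0.0

    def test_kkt_conditions_hold(self, rng):
        for _ in range(10):
            S = _random_corr(rng, 6)
            lam = rng.uniform(0.01, 0.5)
            est = graphical_lasso(S, lam=lam, tol=1e-7)
            assert kkt_violation(S, est) < 1e-4

    def test_matches_independent_solver(self, rng):
        """Cross-check against the reference coordinate-descent in sklearn."""
        from sklearn.covariance import graphical_lasso as sk_glasso

        for _ in range(5):
            S = _random_corr(rng, 7)
            lam = rng.uniform(0.05, 0.3)
            est = graphical_lasso(S, lam=lam, tol=1e-8)
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, K_sk = sk_glasso(S, alpha=lam, tol=1e-9, max_iter=2000)
            assert np.abs(est.precision - K_sk).max() < 5e-3

    def test_edge_set_monotone_in_lambda_up_to_zero_crossings(self, rng):
        """Descending the penalty grid only grows the edge set, except for
        coefficients that genuinely cross zero along the lasso path (those
        are vanishingly small just before they disappear)."""
        S = _random_corr(rng, 8)
        lam_max = np.max(np.abs(S - np.eye(8)))
        grid = np.geomspace(lam_max, 0.01 * lam_max, 30)
        prev_edges, prev_K, prev_lam = None, None, None
        for lam in grid:
            K = graphical_lasso(S, float(lam)).precision
            edges = {
                (i, j) for i in range(8) for j in range(i + 1, 8) if abs(K[i, j]) > 1e-8
            }
            if prev_edges is not None:
                for lost in prev_edges - edges:
                    mid = graphical_lasso(S, float(np.sqrt(lam * prev_lam)))
                    assert abs(mid.precision[lost]) < abs(prev_K[lost]) + 1e-8, (
                        f"edge {lost} vanished without crossing zero"
                    )
                    assert abs(prev_K[lost]) < 0.05
            prev_edges, prev_K, prev_lam = edges, K, float(lam)

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            graphical_lasso(bad, lam=0.1)


class TestBicScore:
    def test_identity_example(self):
        est = PrecisionEstimate(np.eye(2), 0.0)
        assert bic_score(est, np.eye(2), n=100) == pytest.approx(200.0)

    def test_edge_term_counts_nonzero_offdiagonals(self):
        K = np.array([[1.0, -0.2], [-0.2, 1.0]])
        est = PrecisionEstimate(K, 0.0)
        sign, logdet = np.linalg.slogdet(K)
        expected = -2 * (50.0 * (logdet - np.trace(np.eye(2) @ K))) + np.log(100)
        assert bic_score(est, np.eye(2), n=100) == pytest.approx(expected)

    def test_singular_precision_rejected(self):
        est = PrecisionEstimate(np.zeros((2, 2)), 0.0)
        with pytest.raises(np.linalg.LinAlgError):
            bic_score(est, np.eye(2), n=10)

    def test_bic_favours_true_sparsity_on_simulated_data(self):
        """On data from a sparse precision, BIC at the true edge set beats the
        saturated model in most replicates."""
        p = 5
        K_true = np.eye(p)
        K_true[0, 1] = K_true[1, 0] = -0.4
        cov = np.linalg.inv(K_true)
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.multivariate_normal(np.zeros(p), cov, size=1000)
            S = np.corrcoef(x.T)
            from netpsych._glasso import support_refit

            sup_true = np.abs(K_true) > 0
            np.fill_diagonal(sup_true, False)
            K_hat, _ = support_refit(S, sup_true)
            bic_true = bic_score(PrecisionEstimate(K_hat, 0.0), S, 1000)
            bic_full = bic_score(PrecisionEstimate(np.linalg.inv(S), 0.0), S, 1000)
            wins += bic_true < bic_full
        assert wins > 10


class TestSelectPenalty:
    def test_identity_matrix_degenerate_grid(self):
        lam, est = select_penalty(np.eye(3), n=50)
        assert np.allclose(est.precision, np.eye(3))

    def test_grid_size_one_returns_lambda_max_fit(self):
        lam, est = select_penalty(S2, n=50, grid_size=1)
        assert lam == pytest.approx(0.5)
        assert est.edge_count() == 0

    def test_structure_recovery_six_nodes(self):
        """BIC-selected support equals the 4 true edges in most seeds."""
        p = 6
        true_edges = [(0, 1), (1, 2), (3, 4), (4, 5)]
        K = np.eye(p)
        for i, j in true_edges:
            K[i, j] = K[j, i] = -0.4
        assert np.linalg.eigvalsh(K).min() > 0
        cov = np.linalg.inv(K)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = rng.multivariate_normal(np.zeros(p), cov, size=2000)
            S = np.corrcoef(x.T)
            _, est = select_penalty(S, n=2000)
            found = {
                (i, j)
                for i in range(p)
                for j in range(i + 1, p)
                if abs(est.precision[i, j]) > 1e-8
            }
            hits += found == set(true_edges)
        assert hits > 10


class TestPrecisionToPartial:
    def test_worked_two_node_example(self):
        est = PrecisionEstimate(np.array([[4 / 3, -2 / 3], [-2 / 3, 4 / 3]]), 0.0)
        net = precision_to_partial(est)
        assert net.weights[0, 1] == pytest.approx(0.5)
        assert np.all(np.diag(net.weights) == 0)

    def test_diagonal_precision_gives_empty_network(self):
        net = precision_to_partial(PrecisionEstimate(np.diag([2.0, 3.0, 1.0]), 0.0))
        assert net.edge_count() == 0

    def test_sign_flip_contract(self):
        K = np.array([[1.0, 0.3], [0.3, 1.0]])
        net = precision_to_partial(PrecisionEstimate(K, 0.0))
        assert net.weights[0, 1] < 0

    def test_matches_recursive_partial_correlation_formula(self):
        """3-variable oracle: r_xy.z = (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2))."""
        r_xy, r_xz, r_yz = 0.5, 0.4, 0.3
        R = np.array([[1, r_xy, r_xz], [r_xy, 1, r_yz], [r_xz, r_yz, 1.0]])
        net = precision_to_partial(PrecisionEstimate(np.linalg.inv(R), 0.0))
        oracle = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        assert net.weights[0, 1] == pytest.approx(oracle, abs=1e-9)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            precision_to_partial(PrecisionEstimate(np.diag([1.0, -1.0]), 0.0))


class TestEstimateNetwork:
    def test_tiny_sample_runs_without_crashing(self):
        variables = [
            VariableSpec("a", "continuous", bounds=(0, 10)),
            VariableSpec("b", "continuous", bounds=(0, 10)),
            VariableSpec("o", "ordinal", levels=3, bounds=(0, 2)),
        ]
        spec = GroupSpec(
            "G", 5, variables, np.eye(3), {"o": np.array([-0.5, 0.5])}
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = generate_group_sample(spec, seed=12)
        net = estimate_network(table)
        assert net.p == 3  # may be empty; must not crash

    def test_filter_stage_validated(self, td_table):
        with pytest.raises(ValueError, match="filter_stage"):
            estimate_network(td_table, filter_stage="bogus")

    def test_stage_log_recorded(self, td_table):
        net = estimate_network(td_table)
        assert {"filter_stage", "n_correlations_zeroed", "lambda", "edge_count"} <= set(
            net.stages
        )
        assert net.stages["edge_count"] == net.edge_count()
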