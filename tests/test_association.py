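"""Mixed-type correlation estimators and matrix plumbing."""

import numpy as np
import pytest
from scipy import stats

from netpsych.association import (
    mixed_correlation_matrix,
    nearest_psd,
    pearson_corr,
    polychoric_corr,
    polyserial_corr,
    significance_filter,
)
from netpsych.datagen import MeasureTable, VariableSpec

import pandas as pd


def _pearson_oracle(x, y):
    """Direct sum-formula product-moment correlation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


class TestPearson:
    def test_perfect_correlation(self):
        r, p = pearson_corr([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        r, _ = pearson_corr([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, _ = pearson_corr([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 4.0, 3.0])
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_agrees_with_sum_formula_oracle(self, rng):
        for _ in range(20):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30) + 0.5 * x
            r, _ = pearson_corr(x, y)
            assert r == pytest.approx(_pearson_oracle(x, y), abs=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _latent_ordinal_pair(rng, rho, thr_x, thr_y, n):
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    return np.digitize(z[:, 0], thr_x), np.digitize(z[:, 1], thr_y)


class TestPolychoric:
    def test_balanced_independent_table_gives_zero(self):
        x = np.repeat([0, 0, 1, 1], 25)
        y = np.tile([0, 1], 50)
        r, p = polychoric_corr(x, y)
        assert r == pytest.approx(0.0, abs=1e-6)
        assert p > 0.9

    def test_diagonal_table_hits_clip_boundary(self):
        x = np.repeat([0, 1], 50)
        r, p = polychoric_corr(x, x)
        assert r == pytest.approx(0.999, abs=1e-9)
        assert p == 0.0

    def test_monte_carlo_recovery(self, rng):
        x, y = _latent_ordinal_pair(rng, 0.5, [0.0], [-0.5, 0.5], 10_000)
        r, p = polychoric_corr(x, y)
        assert r == pytest.approx(0.5, abs=0.05)
        assert p < 1e-6

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="single observed category"):
            polychoric_corr(np.zeros(20, dtype=int), np.tile([0, 1], 10))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            polychoric_corr(np.array([]), np.array([]))

    @pytest.mark.parametrize("rho", [-0.6, -0.3, 0.0, 0.3, 0.6])
    def test_recovery_across_latent_correlations(self, rho):
        """Two-step ML recovers the generating latent correlation closely."""
        rng = np.random.default_rng(1000 + int(rho * 10))
        x, y = _latent_ordinal_pair(rng, rho, [-0.6, 0.4], [-0.2, 0.9], 10_000)
        r, _ = polychoric_corr(x, y)
        assert abs(r - rho) < 0.02


class TestPolyserial:
    def test_median_split_of_itself_recovers_strong_rho(self, rng):
        x = rng.standard_normal(5000)
        y = (x > np.median(x)).astype(int)
        r, p = polyserial_corr(x, y)
        assert r >= 0.95
        assert p < 1e-10

    def test_independent_pair_near_zero(self, rng):
        x = rng.standard_normal(10_000)
        y = rng.integers(0, 3, size=10_000)
        r, p = polyserial_corr(x, y)
        assert abs(r) < 0.05

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            polyserial_corr(np.ones(10), np.tile([0, 1], 5))

    def test_moderate_latent_correlation_recovered(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=10_000)
        y = np.digitize(z[:, 1], [-0.5, 0.5])
        r, _ = polyserial_corr(z[:, 0], y)
        assert r == pytest.approx(0.4, abs=0.03)


def _mixed_table(rng, n=120):
    variables = [
        VariableSpec("cont1", "continuous", bounds=(0, 36)),
        VariableSpec("wide", "ordinal", levels=15, bounds=(0, 14)),  # continuous-like
        VariableSpec("ord1", "ordinal", levels=6, bounds=(0, 5)),
        VariableSpec("ord2", "ordinal", levels=5, bounds=(0, 4)),
    ]
    z = rng.multivariate_normal(np.zeros(4), np.eye(4) * 0.6 + 0.4, size=n)
    data = pd.DataFrame(
        {
            "group": "G",
            "cont1": 18 + 6 * z[:, 0],
            "wide": np.clip(np.round(7 + 2.3 * z[:, 1]), 0, 14).astype(int),
            "ord1": np.digitize(z[:, 2], [-1.2, -0.6, 0, 0.6, 1.2]),
            "ord2": np.digitize(z[:, 3], [-1, 0, 0.8]),
        }
    )
    return MeasureTable(data, variables)


class TestMixedCorrelationMatrix:
    def test_method_dispatch_on_declared_types(self, rng):
        assoc = mixed_correlation_matrix(_mixed_table(rng))
        names = assoc.names
        m = {(a, b): assoc.method[names.index(a), names.index(b)] for a in names for b in names if a != b}
        assert m[("cont1", "wide")] == "pearson"  # >10 levels treated continuous
        assert m[("cont1", "ord1")] == "polyserial"
        assert m[("wide", "ord2")] == "polyserial"
        assert m[("ord1", "ord2")] == "polychoric"

    def test_symmetry_and_unit_diagonal(self, rng):
        assoc = mixed_correlation_matrix(_mixed_table(rng))
        assert np.array_equal(assoc.r, assoc.r.T)
        assert np.allclose(np.diag(assoc.r), 1.0)
        assert np.array_equal(assoc.method, assoc.method.T)

    def test_permutation_equivariance(self, rng):
        table = _mixed_table(rng)
        assoc = mixed_correlation_matrix(table)
        perm = [2, 0, 3, 1]
        permuted = MeasureTable(
            table.data[["group"] + [table.names[i] for i in perm]],
            [table.variables[i] for i in perm],
        )
        assoc_p = mixed_correlation_matrix(permuted)
        assert np.allclose(assoc_p.r, assoc.r[np.ix_(perm, perm)], atol=1e-12)

    def test_constant_column_named_in_error(self, rng):
        table = _mixed_table(rng)
        data = table.data.copy()
        data["ord1"] = 3
        with pytest.raises(ValueError, match="ord1"):
            mixed_correlation_matrix(MeasureTable(data, table.variables))


def _assoc_from_r(r_vals, n):
    """Build an AssociationMatrix whose p-values come from the t transform."""
    from netpsych.association import AssociationMatrix

    p = len(r_vals) + 1
    r = np.eye(p)
    pv = np.zeros((p, p))
    for k, rv in enumerate(r_vals, start=1):
        t = rv * np.sqrt((n - 2) / (1 - rv**2))
        pval = 2 * stats.t.sf(abs(t), n - 2)
        r[0, k] = r[k, 0] = rv
        pv[0, k] = pv[k, 0] = pval
    method = np.full((p, p), "pearson", dtype=object)
    return AssociationMatrix([f"v{i}" for i in range(p)], r, method, pv, n)


class TestSignificanceFilter:
    def test_weak_correlation_zeroed_strong_retained_at_n157(self):
        # at n=157 the two-sided alpha=0.05 critical |r| is about 0.157
        assoc = _assoc_from_r([0.10, 0.30], n=157)
        filtered, n_zeroed = significance_filter(assoc, alpha=0.05)
        assert filtered.r[0, 1] == 0.0 and filtered.r[1, 0] == 0.0
        assert filtered.r[0, 2] == pytest.approx(0.30)
        assert n_zeroed == 1

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 1.5])
    def test_alpha_bounds_enforced(self, alpha):
        assoc = _assoc_from_r([0.2], n=50)
        with pytest.raises(ValueError, match="alpha"):
            significance_filter(assoc, alpha=alpha)

    def test_diagonal_untouched(self):
        assoc = _assoc_from_r([0.01], n=20)
        filtered, _ = significance_filter(assoc)
        assert np.allclose(np.diag(filtered.r), 1.0)


class TestNearestPsd:
    def test_psd_input_unchanged(self):
        r = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert np.allclose(nearest_psd(r), r, atol=1e-12)

    def test_identity_unchanged(self):
        assert np.allclose(nearest_psd(np.eye(4)), np.eye(4), atol=1e-15)

    def test_indefinite_input_repaired(self):
        r = np.full((3, 3), -0.9)
        np.fill_diagonal(r, 1.0)
        out = nearest_psd(r)
        assert np.linalg.eigvalsh(out).min() >= 0
        assert np.allclose(np.diag(out), 1.0)
        assert np.allclose(out, out.T)

    def test_idempotent(self):
        r = np.full((3, 3), -0.9)
        np.fill_diagonal(r, 1.0)
        once = nearest_psd(r)
        assert np.allclose(nearest_psd(once), once, atol=1e-12)

    def test_asymmetric_rejected(self):
        r = np.eye(3)
        r[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            nearest_psd(r)
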