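import itertools

import numpy as np
import pytest

import cesdcat as cc


def matrix(rows, ids=None):
    rows = np.asarray(rows)
    ids = ids or [f"q{i+1}" for i in range(rows.shape[1])]
    return cc.ResponseMatrix(rows, ids)


class TestCronbachAlpha:
    def test_identical_columns_give_one(self):
        col = np.array([0, 1, 2, 3, 1, 2])
        data = matrix(np.column_stack([col, col, col]))
        assert cc.cronbach_alpha(data) == pytest.approx(1.0)

    def test_zero_covariance_gives_zero(self):
        data = matrix([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert cc.cronbach_alpha(data) == pytest.approx(0.0)

    def test_worked_table_against_direct_formula(self):
        rows = [[0, 1], [1, 1], [2, 2], [3, 3]]
        data = matrix(rows)
        X = np.asarray(rows, dtype=float)
        k = 2
        expected = k / (k - 1) * (
            1 - X.var(axis=0, ddof=1).sum() / X.sum(axis=1).var(ddof=1)
        )
        assert cc.cronbach_alpha(data) == pytest.approx(expected)

    def test_zero_total_variance_is_error(self):
        with pytest.raises(ValueError):
            cc.cronbach_alpha(matrix([[1, 1], [1, 1], [1, 1]]))


class TestOneFactorCFA:
    def test_unidimensional_data_fits_well(self, unidim_data):
        fit = cc.fit_one_factor_cfa(unidim_data)
        p = unidim_data.n_items
        assert fit.df == p * (p + 1) // 2 - 2 * p
        assert fit.cfi >= 0.99
        assert fit.rmsea <= 0.02
        assert fit.rmsea_ci[0] <= fit.rmsea <= fit.rmsea_ci[1] + 1e-9

    def test_independent_items_null_behaviour(self):
        rng = np.random.default_rng(5)
        data = matrix(rng.integers(0, 4, size=(2000, 8)))
        fit = cc.fit_one_factor_cfa(data)
        # implied inter-item correlations vanish (loadings themselves are
        # unidentified under independence: lambda_j^2 + psi_j = 1 any split)
        implied = np.outer(fit.loadings, fit.loadings)
        assert np.max(np.abs(implied[~np.eye(8, dtype=bool)])) < 0.05
        assert fit.chi_square / fit.df == pytest.approx(1.0, abs=0.35)

    def test_two_factor_structure_detected_as_misfit(self, bank):
        # two independent latent traits driving two item blocks
        t1 = cc.draw_thetas(2000, seed=71)
        t2 = cc.draw_thetas(2000, seed=72)
        block1 = cc.simulate_grm_responses(bank.subset(bank.item_ids[:8]), t1, seed=73)
        block2 = cc.simulate_grm_responses(bank.subset(bank.item_ids[8:]), t2, seed=74)
        data = matrix(np.hstack([block1.values, block2.values]))
        fit = cc.fit_one_factor_cfa(data)
        assert fit.rmsea > 0.05

    def test_three_items_saturated_reproduces_covariances(self):
        rng = np.random.default_rng(9)
        f = rng.normal(size=3000)
        X = np.clip(
            np.round(1.5 + np.outer(f, [0.8, 0.6, 0.7]) + rng.normal(0, 0.6, (3000, 3))),
            0, 3,
        ).astype(int)
        data = matrix(X)
        fit = cc.fit_one_factor_cfa(data)
        assert fit.df == 0
        S = np.corrcoef(data.values.T)
        Sigma = np.outer(fit.loadings, fit.loadings) + np.diag(fit.uniquenesses)
        iu = np.triu_indices(3, 1)
        assert np.allclose(Sigma[iu], S[iu], atol=1e-4)


def brute_force_pair_H(x, y):
    """Oracle: max covariance over all pairings of the two marginals."""
    n = len(x)
    cov = np.cov(x, y, ddof=1)[0, 1]
    best = -np.inf
    for perm in itertools.permutations(range(n)):
        best = max(best, np.cov(x, y[list(perm)], ddof=1)[0, 1])
    return cov / best


class TestMokken:
    def test_perfect_guttman_scale_has_unit_H(self):
        base = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        data = matrix(np.column_stack([base, np.minimum(base + 1, 3), base]))
        res = cc.mokken_scalability(data)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(res.pair_H[off], 1.0)
        assert np.allclose(res.item_H, 1.0)
        assert res.scale_H == pytest.approx(1.0)

    def test_independent_items_scale_H_near_zero(self):
        rng = np.random.default_rng(13)
        data = matrix(rng.integers(0, 4, size=(5000, 6)))
        res = cc.mokken_scalability(data)
        assert abs(res.scale_H) < 0.03

    def test_pair_H_matches_brute_force_coupling(self):
        rows = np.array(
            [[0, 1, 0], [1, 1, 2], [2, 0, 1], [3, 2, 3], [1, 3, 2], [2, 2, 0]]
        )
        data = matrix(rows)
        res = cc.mokken_scalability(data)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            oracle = brute_force_pair_H(rows[:, i], rows[:, j])
            assert res.pair_H[i, j] == pytest.approx(oracle, abs=1e-10)

    def test_scale_H_consistent_with_pair_matrix(self, unidim_data):
        sub = unidim_data.subset(unidim_data.item_ids[:6])
        res = cc.mokken_scalability(sub)
        # scale H is the ratio of summed covariances, recomputable from pairs
        X = sub.values.astype(float)
        cov = np.cov(X, rowvar=False, ddof=1)
        iu = np.triu_indices(6, 1)
        covmax = cov[iu] / res.pair_H[iu]
        assert res.scale_H == pytest.approx(cov[iu].sum() / covmax.sum())

    def test_constant_item_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            cc.mokken_scalability(matrix([[1, 0, 2], [1, 1, 0], [1, 2, 3]]))


class TestMokkenSelection:
    def test_no_removal_when_all_scalable(self, unidim_data):
        res = cc.mokken_item_selection(unidim_data)
        assert res.removed_items == []
        assert res.scale_H > 0.30
        assert (res.item_H >= 0.30).all()

    def test_removal_preserves_remaining_pair_H(self, unidim_data):
        sub = unidim_data.subset(unidim_data.item_ids[:6])
        full = cc.mokken_scalability(sub)
        reduced = cc.mokken_scalability(sub.subset(sub.item_ids[1:]))
        assert np.allclose(
            full.pair_H[1:, 1:][~np.eye(5, dtype=bool)],
            reduced.pair_H[~np.eye(5, dtype=bool)],
        )
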