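import numpy as np
import pytest

import cesdcat as cc
from cesdcat.grm import GRMFit, _log_likelihood


class TestCategoryProbs:
    def test_symmetric_item_at_zero(self):
        item = cc.GRMItem("i", 1.0, [-1.0, 0.0, 1.0])
        p = cc.category_probs(item, 0.0)
        assert np.allclose(p, [0.2689, 0.2311, 0.2311, 0.2689], atol=1e-4)
        assert p[0] == pytest.approx(p[3])
        assert p[1] == pytest.approx(p[2])

    def test_boundary_half_at_threshold(self, bank):
        # P(X >= k) = 1/2 exactly when theta sits on the threshold
        item = bank["q6"]
        p = cc.category_probs(item, item.b[0])
        assert p[0] == pytest.approx(0.5)  # P*_1 = 1 - P_0 = 0.5

    def test_floor_saturation(self, bank):
        p = cc.category_probs(bank["q3"], -50.0)
        assert np.allclose(p, [1, 0, 0, 0], atol=1e-12)

    def test_probabilities_sum_to_one_on_grid(self, bank):
        grid = np.linspace(-8, 8, 161)
        for item in bank:
            total = cc.category_probs(item, grid).sum(axis=1)
            assert np.allclose(total, 1.0, atol=1e-12)


class TestInformation:
    def test_dichotomous_reduction_closed_form(self):
        item = cc.GRMItem("d", 1.0, [0.0])
        assert cc.item_information(item, 0.0) == pytest.approx(0.25)

    def test_nonnegative_on_dense_grid(self, bank):
        grid = np.linspace(-6, 6, 601)
        for item in bank:
            assert (cc.item_information(item, grid) >= 0).all()

    def test_matches_numeric_curvature_of_expected_loglik(self):
        # Fisher information = E[-d2/dtheta2 log P_X(theta)] at the true theta
        item = cc.GRMItem("i", 2.0, [-1.0, 0.0, 1.0])
        theta0, h = 0.5, 1e-4
        p0 = cc.category_probs(item, theta0)
        curv = 0.0
        for k in range(4):
            lp = [
                np.log(cc.category_probs(item, theta0 + d)[k])
                for d in (-h, 0.0, h)
            ]
            curv += p0[k] * -(lp[0] - 2 * lp[1] + lp[2]) / h**2
        assert cc.item_information(item, theta0) == pytest.approx(curv, rel=1e-5)

    def test_additivity_and_order_invariance(self, bank):
        item = bank["q9"]
        twice = cc.ItemBank([item, cc.GRMItem("copy", item.a, item.b)])
        assert cc.test_information(twice, 0.7) == pytest.approx(
            2 * cc.item_information(item, 0.7)
        )
        rev = cc.ItemBank(list(bank)[::-1])
        assert cc.test_information(rev, -1.2) == pytest.approx(
            cc.test_information(bank, -1.2)
        )

    def test_tails_below_centre(self, bank):
        assert cc.test_information(bank, 4.0) < cc.test_information(bank, 0.0)
        assert cc.test_information(bank, -4.0) < cc.test_information(bank, 0.0)

    def test_info_curve_se(self, bank):
        curve = cc.info_curve(bank, np.linspace(-2, 2, 5))
        assert np.allclose(curve["se"], 1 / np.sqrt(curve["information"]))


def grid_argmax_ml(bank, resp):
    grid = np.arange(-4, 4 + 1e-9, 1e-4)
    ll = _log_likelihood(bank.subset(list(resp)), resp, grid)
    return grid[int(np.argmax(ll))]


class TestScoring:
    def test_ml_matches_grid_search_single_item(self):
        b = cc.ItemBank([cc.GRMItem("i", 1.0, [-1.0, 0.0, 1.0])])
        est = cc.score_ml(b, {"i": 1})
        assert est.theta == pytest.approx(grid_argmax_ml(b, {"i": 1}), abs=1e-3)

    def test_ml_matches_grid_search_random_patterns(self, bank):
        rng = np.random.default_rng(77)
        for _ in range(100):
            k = rng.integers(2, len(bank) + 1)
            ids = list(rng.choice(bank.item_ids, size=k, replace=False))
            resp = {i: int(rng.integers(0, 4)) for i in ids}
            xs = np.array(list(resp.values()))
            if (xs == 0).all() or (xs == 3).all():
                continue
            est = cc.score_ml(bank, resp)
            assert est.theta == pytest.approx(grid_argmax_ml(bank, resp), abs=1e-3)

    def test_all_ceiling_clamps_to_bound(self, bank):
        est = cc.score_ml(bank, {i: 3 for i in bank.item_ids})
        assert est.theta == 4.0
        assert not est.converged

    def test_order_invariance(self, bank):
        resp = {"q6": 2, "q3": 0, "q17": 3, "q5": 1}
        fwd = cc.score_ml(bank, resp)
        rev = cc.score_ml(bank, dict(reversed(list(resp.items()))))
        assert fwd.theta == pytest.approx(rev.theta, abs=1e-6)

    def test_map_prior_only(self, bank):
        est = cc.score_map(bank)
        assert (est.theta, est.se) == (0.0, 1.0)
        assert est.method == "MAP"

    def test_map_shrinks_toward_prior_mean(self, bank):
        rng = np.random.default_rng(5)
        for _ in range(20):
            resp = {i: int(rng.integers(0, 4)) for i in bank.item_ids[:5]}
            xs = np.array(list(resp.values()))
            if (xs == 0).all() or (xs == 3).all():
                continue
            ml = cc.score_ml(bank, resp)
            mp = cc.score_map(bank, resp)
            assert abs(mp.theta) <= abs(ml.theta) + 1e-6
            # the prior adds information at the evaluation point (the two
            # raw SEs are not comparable when the estimates sit far apart)
            sub = bank.subset(list(resp))
            assert mp.se < 1 / np.sqrt(cc.test_information(sub, mp.theta))
            if abs(ml.theta - mp.theta) < 0.25:
                assert mp.se < ml.se

    def test_all_floor_map_is_finite_and_converged(self, bank):
        est = cc.score_map(bank, {i: 0 for i in bank.item_ids})
        assert est.converged
        assert -4 < est.theta < 0


class TestCalibration:
    def test_loglik_monotone_and_converged(self, unidim_data):
        fit = cc.fit_grm(
            unidim_data.subset(unidim_data.item_ids[:6]), compute_se=False
        )
        assert fit.converged
        diffs = np.diff(fit.ll_trace)
        assert (diffs >= -1e-6).all()

    def test_parameter_recovery_within_3se(self, bank):
        thetas = cc.draw_thetas(1000, seed=201)
        data = cc.simulate_grm_responses(bank, thetas, seed=202)
        fit = cc.fit_grm(data)
        hits = sum(
            abs(est.a - gen.a) <= 3 * est.se_a
            for est, gen in zip(fit.bank, bank)
        )
        assert hits >= 15  # at least 15/17 slopes inside +-3 SE

    def test_loading_conversion(self, bank):
        assert bank["q6"].loading == pytest.approx(0.91, abs=0.005)
        assert bank["q7"].loading == pytest.approx(0.55, abs=0.005)


class TestYenQ3:
    def test_duplicate_item_has_unit_q3(self, small_bank):
        thetas = cc.draw_thetas(400, seed=1)
        data = cc.simulate_grm_responses(small_bank, thetas, seed=2)
        dup_bank = cc.ItemBank(
            list(small_bank) + [cc.GRMItem("i1copy", 1.0, [-1.0, 0.0, 1.0])]
        )
        values = np.column_stack([data.values, data.values[:, 0]])
        dup = cc.ResponseMatrix(values, ["i1", "i2", "i3", "i1copy"])
        q3 = cc.yen_q3(dup, dup_bank)
        assert q3.q3_matrix[0, 3] == pytest.approx(1.0)

    def test_null_data_unflagged(self, unidim_data, bank):
        q3 = cc.yen_q3(unidim_data, bank)
        off = q3.q3_matrix[~np.eye(17, dtype=bool)]
        assert q3.flagged_pairs == []
        assert off.mean() < 0  # residual correlations are slightly negative


class TestTestlet:
    def test_summed_super_item(self):
        rows = np.array([[0, 1, 2], [3, 3, 0], [1, 2, 1], [2, 0, 3]])
        data = cc.ResponseMatrix(rows, ["q1", "q2", "q3"])
        out = cc.form_testlet(data, ["q1", "q3"])
        assert out.item_ids == ["q1+q3", "q2"]
        assert out.n_categories == 7
        assert np.array_equal(out.column("q1+q3"), rows[:, 0] + rows[:, 2])

    def test_self_testlet_rejected(self):
        data = cc.ResponseMatrix(np.zeros((3, 2), int), ["q1", "q2"])
        with pytest.raises(ValueError, match="duplicate|2 distinct"):
            cc.form_testlet(data, ["q1", "q1"])

    def test_missing_item_rejected(self):
        data = cc.ResponseMatrix(np.zeros((3, 2), int), ["q1", "q2"])
        with pytest.raises(ValueError, match="not in matrix"):
            cc.form_testlet(data, ["q1", "q9"])

    def test_testlet_refit_clears_local_dependence(self, bank):
        design = cc.SimulationDesign(
            bank=bank, n_persons=1500, dependent_pairs=[("q4", "q13", 0.5)], seed=91
        )
        data = cc.make_study_dataset(design)
        merged = cc.form_testlet(data, ["q4", "q13"])
        refit = cc.fit_grm(merged, compute_se=False)
        q3 = cc.yen_q3(merged, refit.bank)
        assert q3.flagged_pairs == []


class TestItemFit:
    def test_nominal_rate_under_null(self, unidim_data, fitted):
        table = cc.item_fit(unidim_data, fitted)
        assert (table["statistic"] >= 0).all()
        assert (table["p"] < 0.05).sum() <= 2  # <= ~10% of 17 items

    def test_wrong_slope_flagged(self):
        gen = cc.ItemBank(
            [
                cc.GRMItem("m", 3.0, [-1.0, 0.0, 1.0]),
                cc.GRMItem("a1", 1.5, [-1.5, -0.5, 1.0]),
                cc.GRMItem("a2", 1.5, [-1.0, 0.5, 1.5]),
                cc.GRMItem("a3", 1.5, [-0.5, 0.3, 2.0]),
                cc.GRMItem("a4", 1.5, [-2.0, 0.0, 1.2]),
            ]
        )
        scored = cc.ItemBank(
            [cc.GRMItem("m", 1.0, [-1.0, 0.0, 1.0])] + list(gen)[1:]
        )
        data = cc.simulate_grm_responses(gen, cc.draw_thetas(2000, seed=55), seed=56)
        table = cc.item_fit(data, GRMFit(scored, None, 0.0, True, 0))
        assert float(table.loc[table.item_id == "m", "p"].iloc[0]) < 0.01
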