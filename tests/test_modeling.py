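"""Statistical protocol components against closed-form and brute-force
oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from sarcohab.errors import (DegenerateInputError, InputError,
                             RankDeficiencyError)
from sarcohab.modeling import (backward_stepwise, candidate_cutoffs,
                               confusion_at, fit_logistic, fit_recipe,
                               five_fold_cv, group_compare,
                               icc_two_way_random, roc_auc, split_cohort,
                               youden_cutoff, youden_index)


class TestSplitCohort:
    def test_exact_six_four_ratio(self):
        labels = [0] * 6 + [1] * 4
        train, val = split_cohort(labels, 0.6, seed=0)
        assert train.size == 6 and val.size == 4
        assert np.sum(np.array(labels)[train]) == 2  # stratified: 40% of 4

    def test_same_seed_identical(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a = split_cohort(labels, 0.6, seed=9)
        b = split_cohort(labels, 0.6, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_set_algebra(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.zeros(rng.integers(5, 30)),
                       np.ones(rng.integers(5, 30))]
        train, val = split_cohort(labels, 0.6, seed=seed)
        assert set(train) | set(val) == set(range(labels.size))
        assert set(train) & set(val) == set()

    def test_tiny_class_rejected(self):
        with pytest.raises(InputError):
            split_cohort([0, 0, 0, 1], 0.6, seed=0)


class TestGroupCompare:
    def test_identical_groups_mann_whitney_p_one(self):
        values = np.r_[[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]].astype(float)
        labels = np.r_[np.zeros(5), np.ones(5)]
        got = group_compare(values, labels)
        assert got.p_value == pytest.approx(1.0)

    def test_welch_t_matches_textbook_formula(self):
        g0 = np.array([4.1, 5.2, 6.3, 5.5, 4.9])
        g1 = np.array([6.8, 7.1, 8.0, 7.5, 6.9])
        values = np.r_[g0, g1]
        labels = np.r_[np.zeros(5), np.ones(5)]
        got = group_compare(values, labels)
        se = np.sqrt(g0.var(ddof=1) / 5 + g1.var(ddof=1) / 5)
        t_manual = (g0.mean() - g1.mean()) / se
        assert got.test == "welch_t"
        assert got.statistic == pytest.approx(t_manual, rel=1e-12)

    def test_chi_square_matches_hand_computation(self):
        # 2x2 table (20,10;10,20): all expected cells 15,
        # chi2 = 4 * 25/15 = 6.667 without continuity correction
        values = np.r_[np.zeros(30), np.ones(30)]
        labels = np.r_[np.zeros(20), np.ones(10), np.zeros(10), np.ones(20)]
        got = group_compare(values, labels, categorical=True)
        assert got.test == "chi_square"
        assert got.statistic == pytest.approx(20 / 3, rel=1e-12)

    def test_fisher_fallback_on_sparse_table(self):
        values = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(4), np.ones(1), np.zeros(1), np.ones(4)]
        got = group_compare(values, labels, categorical=True)
        assert got.test == "fisher"

    def test_constant_feature_degenerate(self):
        with pytest.raises(DegenerateInputError):
            group_compare(np.ones(10), np.r_[np.zeros(5), np.ones(5)])


def _neg_loglik(beta, x, y):
    eta = x @ beta
    return np.sum(np.logaddexp(0, eta)) - y @ eta


class TestFitLogistic:
    def test_antisymmetric_data_zero_intercept(self):
        x = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        y = np.array([1, 0, 1, 0, 0, 1])
        model = fit_logistic(pd.DataFrame({"x": x}), y)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)

    def test_two_by_two_odds_ratio_is_cross_product(self):
        # exposure x group counts a=20, b=10, c=10, d=20 -> OR = 400/100 = 4
        x = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        y = np.r_[np.ones(30), np.zeros(30)]
        model = fit_logistic(pd.DataFrame({"exposed": x}), y)
        assert model.odds_ratios[0] == pytest.approx(4.0, rel=1e-6)
        assert model.coefficients[0] == pytest.approx(np.log(4.0), rel=1e-6)

    def test_matches_independent_optimizer(self):
        rng = np.random.default_rng(2024)
        n = 400
        x = rng.normal(size=(n, 2))
        eta = -0.5 + x @ np.array([1.2, -0.8])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        model = fit_logistic(pd.DataFrame(x, columns=["a", "b"]), y)
        xc = np.c_[np.ones(n), x]
        ref = minimize(_neg_loglik, np.zeros(3), args=(xc, y), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 500})
        np.testing.assert_allclose(np.r_[model.intercept, model.coefficients],
                                   ref.x, atol=1e-6)

    def test_perfect_separation_flagged_not_raised(self):
        x = np.r_[np.linspace(-3, -1, 10), np.linspace(1, 3, 10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        model = fit_logistic(pd.DataFrame({"x": x}), y)
        assert not model.converged

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(RankDeficiencyError):
            fit_logistic(df, (x > 0).astype(int))


class TestBackwardStepwise:
    def _data(self, seed=0, n=500):
        rng = np.random.default_rng(seed)
        signal = rng.normal(size=n)
        noise = rng.normal(size=n)
        eta = 1.5 * signal
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        return pd.DataFrame({"signal": signal, "noise": noise, "y": y})

    def test_single_strong_predictor_kept(self):
        df = self._data()
        model, removed = backward_stepwise(df, "y", ["signal"])
        assert model.predictor_names == ["signal"] and removed == []

    def test_noise_predictor_removed(self):
        df = self._data(seed=3)
        model, removed = backward_stepwise(df, "y", ["signal", "noise"])
        assert model.predictor_names == ["signal"]
        assert removed == ["noise"]

    def test_final_model_all_significant(self):
        df = self._data(seed=5)
        df["noise2"] = np.random.default_rng(11).normal(size=len(df))
        model, _ = backward_stepwise(df, "y",
                                     ["signal", "noise", "noise2"])
        assert np.all(model.p_values <= 0.05) or \
            len(model.predictor_names) == 1

    def test_duplicated_column_rank_error(self):
        df = self._data()
        df["dup"] = df["signal"]
        with pytest.raises(RankDeficiencyError):
            backward_stepwise(df, "y", ["signal", "dup"])


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0

    def test_all_ties_give_half(self):
        res = roc_auc(np.ones(10), np.r_[np.zeros(5), np.ones(5)])
        assert res.auc == 0.5

    def test_four_pair_enumeration(self):
        # pairs: (.5>.1)=1, (.5<.6)=0, (.9>.1)=1, (.9>.6)=1 -> 3/4
        res = roc_auc([0.1, 0.6, 0.5, 0.9], [0, 0, 1, 1])
        assert res.auc == 0.75

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_negation_complements_auc(self, rng):
        scores = rng.normal(size=50)  # continuous: no ties
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert roc_auc(-scores, labels).auc == \
            pytest.approx(1 - roc_auc(scores, labels).auc, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels).auc == \
            pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.tuples(
        # 1e-6 quantisation keeps score gaps far above float absorption,
        # so the +7.25 shift cannot merge distinct scores into ties
        st.floats(-50, 50).map(lambda x: round(x, 6)), st.booleans()),
        min_size=4, max_size=40))
    def test_property_auc_bounds_and_shift_invariance(self, pairs):
        scores = np.array([s for s, _ in pairs])
        labels = np.array([int(l) for _, l in pairs])
        if labels.min() == labels.max():
            labels[0], labels[-1] = 0, 1
        a = roc_auc(scores, labels).auc
        assert 0.0 <= a <= 1.0
        # adding a constant is strictly monotone: AUC unchanged, ties kept
        b = roc_auc(scores + 7.25, labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestYoudenCutoff:
    def test_degenerate_formula_edge_case(self):
        # every score tied: the all-positive call wins ties by sensitivity
        summary = youden_cutoff(np.ones(10), np.r_[np.ones(5), np.zeros(5)])
        assert summary.sensitivity == 1.0
        assert summary.specificity == 0.0
        assert summary.accuracy == 0.5

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_maximiser(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(40), 2)  # duplicates on purpose
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        summary = youden_cutoff(scores, labels)
        best_j = max(
            youden_index(confusion_at(scores, labels, c).sensitivity,
                         confusion_at(scores, labels, c).specificity)
            for c in candidate_cutoffs(scores))
        assert summary.youden == pytest.approx(best_j, abs=1e-12)

    def test_youden_consistent_with_own_counts(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        s = youden_cutoff(scores, labels)
        assert s.youden == pytest.approx(
            s.counts.sensitivity + s.counts.specificity - 1, abs=1e-12)


class TestFiveFoldCv:
    def _table(self, n=100, separable=True, seed=0):
        rng = np.random.default_rng(seed)
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        x = y * 10.0 + rng.normal(size=n) * (0.1 if separable else 100.0)
        return pd.DataFrame({"x": x, "y": y})

    def test_determinism(self):
        df = self._table()
        a = five_fold_cv(df, "y", ["x"], seed=4)
        b = five_fold_cv(df, "y", ["x"], seed=4)
        assert a.fold_aucs == b.fold_aucs

    def test_separable_features_give_perfect_auc(self):
        res = five_fold_cv(self._table(separable=True), "y", ["x"], seed=1)
        assert len(res.fold_aucs) == 5
        assert res.mean_auc == pytest.approx(1.0)

    def test_mean_is_mean_of_folds(self):
        res = five_fold_cv(self._table(seed=2), "y", ["x"], seed=2)
        assert res.mean_auc == pytest.approx(np.mean(res.fold_aucs))

    def test_small_class_rejected(self):
        df = self._table(n=8)
        with pytest.raises(InputError):
            five_fold_cv(df, "y", ["x"], seed=0)


class TestFitRecipe:
    def test_no_survivor_gives_empty_model(self, rng):
        df = pd.DataFrame({"noise": rng.normal(size=60),
                           "y": rng.integers(0, 2, 60)})
        df.loc[:1, "y"] = [0, 1]
        out = fit_recipe(df, "y", ["noise"])
        if out.final_model is not None:  # noise can pass at alpha=0.05
            assert out.screened == ["noise"]
        else:
            assert out.screened == []

    def test_informative_predictor_selected(self):
        rng = np.random.default_rng(12)
        n = 300
        signal = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * signal))).astype(int)
        df = pd.DataFrame({"signal": signal,
                           "noise": rng.normal(size=n), "y": y})
        out = fit_recipe(df, "y", ["signal", "noise"])
        assert "signal" in out.final_model.predictor_names


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.tile(np.array([1.0, 2.0, 3.0, 4.0])[:, None], (1, 3))
        assert icc_two_way_random(x) == pytest.approx(1.0)

    def test_matches_hand_anova_on_toy_matrix(self):
        x = np.array([[1.0, 1.4], [2.0, 1.7], [3.0, 3.5], [4.0, 4.2]])
        n, k = x.shape
        grand = x.mean()
        ms_r = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        ms_c = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        ss_e = ((x - grand) ** 2).sum() \
            - ms_r * (n - 1) - ms_c * (k - 1)
        ms_e = ss_e / ((n - 1) * (k - 1))
        expected = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e
                                    + k * (ms_c - ms_e) / n)
        assert icc_two_way_random(x) == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin_reference(self):
        import pingouin as pg
        rng = np.random.default_rng(8)
        base = rng.normal(10, 3, 12)
        x = np.c_[base + rng.normal(0, 1, 12), base + rng.normal(0, 1, 12)]
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 2),
            "rater": np.tile([0, 1], 12),
            "score": x.ravel()})
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        # two-way random, single measure, absolute agreement
        sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[sel, "ICC"].iloc[0]
        assert icc_two_way_random(x) == pytest.approx(icc2, abs=1e-9)

    def test_uninformative_rater_gives_low_icc(self, rng):
        x = np.c_[np.full(8, 5.0), rng.normal(5, 2, 8)]
        assert abs(icc_two_way_random(x)) < 0.3

    def test_no_subject_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            icc_two_way_random(np.ones((4, 2)))
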