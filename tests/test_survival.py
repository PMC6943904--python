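"""Survival estimation, log-rank/Cox, ROC, qPCR and cohort summaries."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from hfomics.simulate import CohortSpec, generate_cohort
from hfomics.survival import (cohort_summary, cox_univariate, ddct_fold_change,
                              fisher_exact, group_mean_compare, kaplan_meier,
                              log_rank, median_split, percentage, roc_analysis,
                              survival_gene_screen, trapezoid_auc)


class TestMedianSplit:
    def test_even_n_clean_split(self):
        groups = median_split(pd.Series([1, 2, 3, 4]))
        assert list(groups) == ["low", "low", "high", "high"]

    def test_ties_at_median_go_high(self):
        groups = median_split(pd.Series([1, 2, 2, 3]))
        assert list(groups) == ["low", "high", "high", "high"]

    def test_odd_n(self):
        groups = median_split(pd.Series([1, 2, 3]))
        assert list(groups) == ["low", "high", "high"]

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError):
            median_split(pd.Series([2.0, 2.0, 2.0]))


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        km = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_allclose(km.at_risk, [4, 3, 2, 1])

    def test_single_event_drops_to_zero(self):
        km = kaplan_meier([5.0], [1])
        np.testing.assert_allclose(km.survival, [0.0])

    def test_all_censored_flat_at_one(self):
        km = kaplan_meier([1, 2, 3], [0, 0, 0])
        t, s = km.step_function()
        assert list(s) == [1.0]

    def test_censoring_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        e[0] = 1
        km = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for ti, si in zip(km.times, km.survival):
            assert si == pytest.approx(
                float(kmf.survival_function_at_times(ti).iloc[0]), abs=1e-10)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(5, size=25)
        km = kaplan_meier(t, np.ones(25, dtype=int))
        for ti, si in zip(km.times, km.survival):
            assert si == pytest.approx(np.mean(t > ti), abs=1e-12)


class TestLogRank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 2, 3, 4, 5])
        res = log_rank(t, np.ones(5, int), t, np.ones(5, int))
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.statistics import logrank_test
        for _ in range(100):
            na, nb = rng.integers(5, 30, size=2)
            ta = rng.exponential(10, na)
            tb = rng.exponential(rng.uniform(5, 20), nb)
            ea = rng.integers(0, 2, na)
            eb = rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                ea[0] = 1
            res = log_rank(ta, ea, tb, eb)
            ref = logrank_test(ta, tb, ea, eb)
            assert res.chi_square == pytest.approx(ref.test_statistic,
                                                   abs=1e-8)
            assert res.p == pytest.approx(ref.p_value, abs=1e-8)

    def test_invariant_under_group_swap(self, rng):
        ta, tb = rng.exponential(10, 20), rng.exponential(5, 15)
        ea, eb = np.ones(20, int), np.ones(15, int)
        assert log_rank(ta, ea, tb, eb).p == pytest.approx(
            log_rank(tb, eb, ta, ea).p, abs=1e-12)

    def test_needs_an_event(self):
        with pytest.raises(ValueError):
            log_rank([1.0], [0], [2.0], [0])


class TestCox:
    def test_null_covariate_hr_near_one(self, rng):
        t = rng.exponential(10, size=200)
        x = rng.normal(size=200)
        fit = cox_univariate(t, np.ones(200, int), x)
        assert fit.ci_low < 1.0 < fit.ci_high

    def test_matches_grid_search_partial_likelihood(self, rng):
        """Newton solution maximises the Breslow partial likelihood
        computed independently on a fine coefficient grid."""
        n = 30
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.8 * x)))
        e = np.ones(n, int)
        fit = cox_univariate(t, e, x)

        def pll(beta):
            order = np.argsort(t)
            ts, xs = t[order], x[order]
            ll = 0.0
            for i in range(n):
                risk = ts >= ts[i]
                ll += beta * xs[i] - np.log(np.exp(beta * xs[risk]).sum())
            return ll

        grid = np.arange(fit.coef - 0.05, fit.coef + 0.05, 1e-4)
        best = grid[np.argmax([pll(b) for b in grid])]
        assert fit.coef == pytest.approx(best, abs=2e-4)

    def test_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.5 * x)))
        e = rng.integers(0, 2, size=n)
        e[:5] = 1
        fit = cox_univariate(t, e, x)
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert fit.coef == pytest.approx(ref.params_["x"], abs=1e-6)
        assert fit.se == pytest.approx(ref.standard_errors_["x"], abs=1e-6)

    def test_separation_flagged(self):
        # covariate perfectly orders the event times -> monotone likelihood
        t = np.arange(1.0, 13.0)
        x = np.arange(12.0)
        fit = cox_univariate(t, np.ones(12, int), x)
        assert not fit.converged

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate([1.0, 2.0, 3.0], [1, 1, 1], [2.0, 2.0, 2.0])


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([10, 9, 1, 2], ["le_1yr", "le_1yr",
                                           "gt_1yr", "gt_1yr"])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_pairwise_concordance_with_ties(self):
        # positives [3,2] vs negatives [1,2]: (1+1+1+0.5)/4
        res = roc_analysis([3, 2, 1, 2], ["le_1yr", "le_1yr",
                                          "gt_1yr", "gt_1yr"])
        assert res.auc == pytest.approx(0.875)

    def test_auc_complement_under_sign_flip(self, rng):
        v = rng.normal(size=60)
        labels = np.where(rng.random(60) < 0.4, "le_1yr", "gt_1yr")
        a1 = roc_analysis(v, labels).auc
        a2 = roc_analysis(-v, labels).auc
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_concordance_equals_trapezoid_area(self, rng):
        v = np.round(rng.normal(size=80), 1)  # induce ties
        labels = np.where(rng.random(80) < 0.3, "le_1yr", "gt_1yr")
        res = roc_analysis(v, labels)
        assert res.auc == pytest.approx(trapezoid_auc(res.curve), abs=1e-10)

    def test_matches_sklearn_auc(self, rng):
        from sklearn.metrics import roc_auc_score
        v = np.round(rng.normal(size=100), 1)
        y = (rng.random(100) < 0.3).astype(int)
        labels = np.where(y == 1, "le_1yr", "gt_1yr")
        assert roc_analysis(v, labels).auc == pytest.approx(
            roc_auc_score(y, v), abs=1e-12)

    def test_cutoff_ties_broken_toward_lower(self):
        # J is maximal over a range; the smallest optimal cutoff is reported
        res = roc_analysis([5, 4, 2, 1], ["le_1yr", "le_1yr",
                                          "gt_1yr", "gt_1yr"])
        assert res.cutoff == pytest.approx(3.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2], ["le_1yr", "le_1yr"])


class TestGroupMeanCompare:
    def test_identical_groups_p_near_one(self):
        out = group_mean_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["p"] > 0.99

    def test_matches_welch_oracle(self, rng):
        from scipy import stats as sps
        a, b = rng.normal(size=12), rng.normal(1.0, size=9)
        out = group_mean_compare(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert out["p"] == pytest.approx(ref.pvalue, abs=1e-12)
        assert out["sem_a"] == pytest.approx(sps.sem(a), abs=1e-12)

    def test_large_shift_is_significant(self, rng):
        a = rng.normal(3.0, 1.0, size=20)
        b = rng.normal(0.0, 1.0, size=20)
        assert group_mean_compare(a, b)["p"] < 1e-6


class TestDdct:
    def test_zero_ddct_fold_one(self):
        fold = ddct_fold_change([20.0, 20.0], [15.0, 15.0], [True, False])
        assert fold[1] == pytest.approx(1.0)

    def test_minus_two_ddct_fold_four(self):
        # control dCt = 5; sample dCt = 3 -> ddCt = -2 -> fold 4
        fold = ddct_fold_change([20.0, 18.0], [15.0, 15.0], [True, False])
        assert fold[1] == pytest.approx(4.0)

    def test_control_group_centred_at_fold_one(self, rng):
        ct_t = rng.normal(22, 1, size=10)
        ct_r = rng.normal(16, 1, size=10)
        is_ctl = np.array([True] * 5 + [False] * 5)
        fold = ddct_fold_change(ct_t, ct_r, is_ctl)
        # geometric mean of the control folds is 1 by construction
        assert np.exp(np.log(fold[is_ctl]).mean()) == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            ddct_fold_change([20.0], [np.nan], [True])


class TestFisherExact:
    def test_cohort_sex_table(self):
        # 13/21 male HF vs 9/9 male control
        assert round(fisher_exact([[13, 8], [9, 0]]), 2) == 0.07

    def test_balanced_table_p_one(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        assert fisher_exact([[10, 0], [0, 10]]) == pytest.approx(
            2 / comb(20, 10), rel=1e-12)

    def test_matches_hypergeometric_enumeration(self, rng):
        """Two-sided p equals the sum of hypergeometric probabilities of
        all tables with the observed margins that are no more likely."""
        from scipy.stats import hypergeom
        for _ in range(20):
            a, b, c, d = rng.integers(1, 12, size=4)
            n = a + b + c + d
            p_obs = hypergeom.pmf(a, n, a + b, a + c)
            total = 0.0
            for k in range(max(0, a + c - (c + d)), min(a + b, a + c) + 1):
                pk = hypergeom.pmf(k, n, a + b, a + c)
                if pk <= p_obs * (1 + 1e-9):
                    total += pk
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                min(total, 1.0), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [3, 4]])


class TestCohortSummary:
    def test_male_percentage_of_cases(self):
        samples = pd.DataFrame({
            "condition": ["HF"] * 21 + ["control"] * 9,
            "sex": ["male"] * 13 + ["female"] * 8 + ["male"] * 9,
            "age": np.r_[np.full(21, 35.0), np.full(9, 42.0)]
                + np.arange(30) * 0.1,
        })
        out = cohort_summary(samples)
        male = out[(out.covariate == "sex") & (out.category == "male")]
        assert male.iloc[0]["percent"] == pytest.approx(61.9, abs=0.05)

    def test_category_percentages_sum_to_100(self):
        samples = pd.DataFrame({
            "condition": ["HF"] * 10,
            "nyha": ["II"] * 2 + ["III"] * 3 + ["IV"] * 5,
        })
        out = cohort_summary(samples)
        assert out["percent"].sum() == pytest.approx(100.0)

    def test_empty_covariate_omitted(self):
        samples = pd.DataFrame({"condition": ["HF", "control"],
                                "lvef": [np.nan, np.nan]})
        out = cohort_summary(samples)
        assert "lvef" not in set(out["covariate"])

    def test_percentage_helper(self):
        assert percentage(13, 21) == 61.9
        assert percentage(13, 33, 2) == 39.39


class TestSurvivalScreen:
    def test_planted_marker_negative_and_significant(self):
        hits = 0
        for seed in range(10):
            ds = generate_cohort(CohortSpec(n_hf=50, n_mrna=100, n_lnc=30,
                                            n_mir=30, planted_edges=3,
                                            planted_ffls=0, n_fibrosis=18,
                                            survival_gamma=0.6,
                                            seed=500 + seed))
            scr = survival_gene_screen(ds.mrna.hf_samples(),
                                       ds.survival).set_index("gene")
            row = scr.loc[ds.truth.true_marker]
            hits += (row["r"] < 0) and (row["p"] < 0.05)
        assert hits >= 9

    def test_null_gene_correlations_small(self, default_cohort):
        scr = survival_gene_screen(default_cohort.mrna.hf_samples(),
                                   default_cohort.survival)
        null = scr[scr.gene != default_cohort.truth.true_marker]
        assert null["r"].abs().median() < 0.4

    def test_matches_formula_oracle(self, default_cohort):
        ds = default_cohort
        scr = survival_gene_screen(ds.mrna.hf_samples(), ds.survival)
        surv = ds.survival[ds.survival.stream == "hf_onset"]
        t = surv.set_index("patient_id")["time_months"]
        g = scr.iloc[0]["gene"]
        x = ds.mrna.hf_samples().values.loc[g, t.index].to_numpy()
        r0 = np.corrcoef(x, t.to_numpy())[0, 1]
        assert scr.iloc[0]["r"] == pytest.approx(r0, abs=1e-12)


class TestMedianSplitPipeline:
    def test_high_marker_group_has_poorer_survival(self):
        """Planted-marker median split: the high-expression group sits
        below the low group and log-rank rejects in most replicates at
        gamma = 0.8, n = 21."""
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            ds = generate_cohort(CohortSpec(seed=900 + seed,
                                            survival_gamma=0.8))
            surv = ds.survival[ds.survival.stream == "hf_onset"]
            surv = surv.set_index("patient_id")
            expr = ds.mrna.hf_samples().values.loc[ds.truth.true_marker]
            groups = median_split(expr)
            hi = groups.index[groups == "high"]
            lo = groups.index[groups == "low"]
            res = log_rank(surv.loc[hi, "time_months"], surv.loc[hi, "event"],
                           surv.loc[lo, "time_months"], surv.loc[lo, "event"])
            km_hi = kaplan_meier(surv.loc[hi, "time_months"],
                                 surv.loc[hi, "event"])
            km_lo = kaplan_meier(surv.loc[lo, "time_months"],
                                 surv.loc[lo, "event"])
            # compare survival at the high group's median event time
            t_mid = np.median(km_hi.times)
            s_hi = km_hi.survival[km_hi.times <= t_mid][-1]
            s_lo_arr = km_lo.survival[km_lo.times <= t_mid]
            s_lo = s_lo_arr[-1] if s_lo_arr.size else 1.0
            hits += (res.p < 0.05) and (s_hi <= s_lo)
        assert hits / n_rep >= 0.9
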