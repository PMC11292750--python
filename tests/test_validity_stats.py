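"""Validity battery: rank statistics against independent oracles, ROC/AUC
identities, DeLong intervals against a frozen pROC reference, logistic IRLS
against statsmodels, and the subgroup report's arithmetic."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
import statsmodels.api as sm
from scipy.special import expit

from daoh90 import (DataError, DegenerateInputError, FactorDef,
                    SeparationWarning, UsageError, dichotomize_mrs,
                    fit_logistic, mann_whitney, mrs_distribution_summary,
                    roc_auc, spearman, subgroup_table)

# mRS-90 distribution of a 1278-patient reperfusion-therapy cohort
# (categories 0..6); 691 of them are functionally independent (mRS 0-2).
COHORT_MRS_COUNTS = (226, 256, 209, 232, 124, 39, 192)


def _expand(counts):
    return np.repeat(np.arange(7), counts)


class TestSpearman:
    def test_perfect_antitone(self):
        x = np.arange(20.0)
        rho, p = spearman(x, -x)
        assert rho == pytest.approx(-1.0)
        assert p < 1e-6

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(3)
        for n in (5, 12, 40):
            x = rng.normal(size=n)
            y = np.round(rng.normal(size=n), 1)  # induce some ties
            rho, _ = spearman(x, y)
            oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_exact_small_sample_p_is_permutation_fraction(self):
        # n = 4, x = y: rho = 1; permutations of 4 ranks give |rho| = 1
        # twice (identity and full reversal) -> p = 2/24
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_pairwise_deletion(self):
        x = [1.0, 2.0, None, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 9.0, 5.0, None, 7.0]
        rho, _ = spearman(x, y)
        rho_ref, _ = spearman([1, 2, 4, 6], [2, 1, 5, 7])
        assert rho == pytest.approx(rho_ref, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman([1, 2], [3, 4])               # too few pairs
        with pytest.raises(DegenerateInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])   # constant variable


class TestMannWhitney:
    def test_identical_groups_symmetric(self):
        vals = [3, 1, 4, 1, 5, 9, 3, 1, 4, 1, 5, 9]
        grp = [1] * 6 + [0] * 6
        u, p = mann_whitney(vals, grp)
        assert u == pytest.approx(18.0)   # n1*n2/2
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        u, p = mann_whitney([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1)    # 2 of the 20 arrangements

    def test_u_equals_brute_force_pairwise_count(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n1, n2 = rng.integers(2, 12, 2)
            x = rng.integers(0, 6, n1).astype(float)
            y = rng.integers(0, 6, n2).astype(float)
            u, _ = mann_whitney(np.r_[x, y],
                                np.r_[np.ones(n1), np.zeros(n2)])
            brute = sum(1.0 if a > b else 0.5 if a == b else 0.0
                        for a in x for b in y)
            assert u == pytest.approx(brute, abs=1e-9)

    def test_large_sample_p_matches_scipy_corrected_normal(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 90, 40).astype(float)
        g = rng.integers(0, 2, 40).astype(float)
        if g.sum() in (0, 40):
            g[0] = 1 - g[0]
        u, p = mann_whitney(x, g)
        ref = sps.mannwhitneyu(x[g == 1], x[g == 0], method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            mann_whitney([1, 2, 3], [1, 1, 1])


class TestDichotomizeAndSummary:
    def test_threshold_semantics(self):
        assert dichotomize_mrs(2, 2) is True
        assert dichotomize_mrs(3, 2) is False

    def test_bad_cutpoint_rejected(self):
        with pytest.raises(UsageError):
            dichotomize_mrs(2, 5)

    def test_functional_independence_from_cohort_distribution(self):
        s = mrs_distribution_summary(_expand(COHORT_MRS_COUNTS))
        assert s["n"] == 1278
        assert s["functional_independence_count"] == 691
        assert round(s["functional_independence_percent"]) == 54

    def test_small_examples(self):
        s = mrs_distribution_summary([0, 0, 6])
        assert s["functional_independence_count"] == 2
        assert s["functional_independence_percent"] == pytest.approx(200 / 3)
        assert mrs_distribution_summary([6, 6])[
            "functional_independence_count"] == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            mrs_distribution_summary([0, 7])


class TestRoc:
    def test_perfect_and_constant_scores(self):
        labels = [1, 1, 1, 0, 0, 0]
        assert roc_auc([9, 8, 7, 2, 1, 0], labels).auc == pytest.approx(1.0)
        assert roc_auc([5, 5, 5, 5, 5, 5], labels).auc == pytest.approx(0.5)

    def test_auc_equals_pairwise_concordance_and_mw_u(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n = int(rng.integers(10, 31))
            scores = rng.integers(0, 15, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            r = roc_auc(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            brute = sum(1.0 if a > b else 0.5 if a == b else 0.0
                        for a in pos for b in neg)
            assert r.auc * r.n_pos * r.n_neg == pytest.approx(brute, abs=1e-9)
            u, _ = mann_whitney(scores, labels)
            assert r.auc * r.n_pos * r.n_neg == pytest.approx(u, abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        base = roc_auc(scores, labels).auc
        for f in (np.exp, lambda s: s**3, lambda s: 5 * s - 2):
            assert roc_auc(f(scores), labels).auc == pytest.approx(base,
                                                                   abs=1e-12)

    def test_delong_ci_matches_frozen_proc_reference(self):
        # reference interval computed once with R pROC (ci.auc, DeLong)
        scores = [8, 70, 59, 39, 39, 78, 7, 63, 18, 8, 47, 88, 66, 69, 65,
                  71, 46, 11, 76, 40, 45, 33, 16, 84, 71, 58, 36, 74, 49, 40]
        labels = [1, 0, 1, 0, 0, 0, 1, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 1, 1,
                  1, 1, 1, 1, 1, 0, 1, 0, 0, 1, 0]
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(0.459821428571, abs=1e-9)
        assert r.ci_low == pytest.approx(0.243793568139, abs=1e-9)
        assert r.ci_high == pytest.approx(0.675849289004, abs=1e-9)

    def test_bootstrap_ci_is_seeded_and_brackets_auc(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=80) + rng.integers(0, 2, 80)
        labels = (scores + rng.normal(size=80) > 0.5).astype(int)
        r1 = roc_auc(scores, labels, ci="bootstrap", seed=1, n_boot=200)
        r2 = roc_auc(scores, labels, ci="bootstrap", seed=1, n_boot=200)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.auc <= r1.ci_high

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(15)
        r = roc_auc(rng.normal(size=50), rng.integers(0, 2, 50))
        fpr = [c[0] for c in r.curve_points]
        tpr = [c[1] for c in r.curve_points]
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    def test_one_class_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestLogistic:
    def test_intercept_only_balanced(self):
        rng = np.random.default_rng(20)
        X = pd.DataFrame({"noise": rng.normal(size=200)})
        y = np.r_[np.ones(100), np.zeros(100)]
        fit = fit_logistic(X, y)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=0.1)
        assert fit.c_statistic == pytest.approx(0.5, abs=0.1)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame({"a": rng.normal(size=300),
                          "b": rng.integers(0, 2, 300).astype(float)})
        y = (rng.random(300) < expit(0.3 + 0.8 * X["a"] - 0.5 * X["b"])
             ).astype(float)
        fit = fit_logistic(X, y)
        sm_fit = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.coefficients["intercept"] == pytest.approx(
            sm_fit.params["const"], abs=1e-6)
        assert fit.coefficients["a"] == pytest.approx(sm_fit.params["a"],
                                                      abs=1e-6)
        assert fit.std_errors["b"] == pytest.approx(sm_fit.bse["b"], rel=1e-4)

    def test_separation_is_warned_not_silent(self):
        X = pd.DataFrame({"flag": np.r_[np.ones(20), np.zeros(20)]})
        y = np.r_[np.ones(20), np.zeros(20)]
        with pytest.warns(SeparationWarning):
            fit = fit_logistic(X, y)
        assert fit.separation

    def test_listwise_deletion_reported(self):
        rng = np.random.default_rng(22)
        X = pd.DataFrame({"a": rng.normal(size=50)})
        X.loc[:4, "a"] = np.nan
        y = rng.integers(0, 2, 50)
        assert fit_logistic(X, y).n_used == 45

    def test_degenerate_inputs_rejected(self):
        X = pd.DataFrame({"a": np.arange(20.0)})
        with pytest.raises(DegenerateInputError):
            fit_logistic(X, np.ones(20))          # constant outcome
        with pytest.raises(DegenerateInputError):
            fit_logistic(pd.DataFrame({"a": np.ones(20)}),
                         np.r_[np.ones(10), np.zeros(10)])  # constant feature
        with pytest.raises(DegenerateInputError):
            fit_logistic(X.head(5), np.r_[np.ones(3), np.zeros(2)])


class TestSubgroupTable:
    def _frame(self, rng, n=400):
        daoh = rng.integers(0, 91, n).astype(float)
        mrs = rng.integers(0, 7, n).astype(float)
        flag = rng.integers(0, 2, n).astype(float)
        return pd.DataFrame({"patient_id": np.arange(n), "daoh": daoh,
                             "mrs90": mrs, "flag": flag,
                             "age": rng.normal(70, 10, n)})

    def test_difference_sign_convention_and_relabel_flip(self):
        rng = np.random.default_rng(30)
        df = self._frame(rng)
        rows = subgroup_table(df, [FactorDef("flag", "flag")])
        df2 = df.assign(flag=1 - df["flag"])
        flipped = subgroup_table(df2, [FactorDef("flag", "flag")])
        assert rows[0].daoh_difference == pytest.approx(
            -flipped[0].daoh_difference)
        assert rows[0].mrs_difference == pytest.approx(
            -flipped[0].mrs_difference)
        assert rows[0].daoh_p == pytest.approx(flipped[0].daoh_p)
        assert rows[0].daoh_difference == pytest.approx(
            rows[0].median_daoh_present - rows[0].median_daoh_absent)

    def test_self_split_gives_maximal_separation(self):
        rng = np.random.default_rng(31)
        df = self._frame(rng)
        df["self"] = (df["daoh"] > df["daoh"].median()).astype(float)
        row = subgroup_table(df, [FactorDef("self", "self")])[0]
        assert row.daoh_p < 1e-10
        assert row.daoh_difference > 0

    def test_null_factor_differences_are_small(self):
        rng = np.random.default_rng(32)
        diffs, ps = [], []
        for _ in range(20):
            df = self._frame(rng)
            row = subgroup_table(df, [FactorDef("flag", "flag")])[0]
            diffs.append(row.daoh_difference)
            ps.append(row.daoh_p)
        assert abs(np.median(diffs)) < 6
        assert 0.1 < np.mean(np.array(ps) < 0.5) < 0.9  # p roughly uniform

    def test_single_level_factor_marked_unavailable(self):
        rng = np.random.default_rng(33)
        df = self._frame(rng)
        df["const"] = 1.0
        row = subgroup_table(df, [FactorDef("const", "const")])[0]
        assert row.daoh_difference is None
        assert row.n_absent == 0

    def test_continuous_factor_median_split(self):
        rng = np.random.default_rng(34)
        df = self._frame(rng)
        row = subgroup_table(df, [FactorDef("age", "age", "continuous")])[0]
        med = df["age"].median()
        assert row.n_present == int((df["age"] >= med).sum())

    def test_missing_factor_values_excluded_only_for_that_row(self):
        rng = np.random.default_rng(35)
        df = self._frame(rng)
        df.loc[:49, "flag"] = np.nan
        rows = subgroup_table(df, [FactorDef("flag", "flag"),
                                   FactorDef("age", "age", "continuous")])
        assert rows[0].n_present + rows[0].n_absent == 350
        assert rows[1].n_present + rows[1].n_absent == 400

    def test_worked_example_differences_from_reported_medians(self):
        """Median-difference arithmetic on the reported subgroup medians:
        recanalization 71 vs 24 -> +47; ICU 7 vs 74 -> -67; early
        neurological improvement 82 vs 51 -> +31."""
        for present, absent, expected in ((71, 24, 47), (7, 74, -67),
                                          (82, 51, 31)):
            # two synthetic levels engineered to have exactly these medians
            lvl_p = np.clip(present + np.arange(-2.0, 3.0), 0, 90)
            lvl_a = np.clip(absent + np.arange(-2.0, 3.0), 0, 90)
            df = pd.DataFrame({
                "daoh": np.r_[lvl_p, lvl_a],
                "mrs90": np.resize([0, 1, 2, 3, 4], 10).astype(float),
                "f": np.r_[np.ones(5), np.zeros(5)]})
            row = subgroup_table(df, [FactorDef("f", "f")])[0]
            assert row.median_daoh_present == present
            assert row.median_daoh_absent == absent
            assert row.daoh_difference == expected
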