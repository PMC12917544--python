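"""Group statistics: ANOVA, Tukey, Wilcoxon, regression, Bonferroni."""

from itertools import product

import numpy as np
import pytest
from scipy import stats as sst

from nirsvar.stats import (
    anova_oneway,
    tukey_hsd,
    wilcoxon_signed_rank,
    linear_regression,
    adjust_pvalues,
)


class TestAnova:
    def test_identical_groups_null_result(self):
        res = anova_oneway({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.F == pytest.approx(0.0)
        assert res.partial_eta2 == pytest.approx(0.0)

    def test_hand_worked_sums_of_squares(self):
        """Independent SS arithmetic on three shifted triples."""
        groups = {"a": [1.0, 2, 3], "b": [2.0, 3, 4], "c": [3.0, 4, 5]}
        vals = np.concatenate(list(groups.values()))
        grand = vals.mean()
        ss_b = sum(3 * (np.mean(g) - grand) ** 2 for g in groups.values())
        ss_w = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups.values())
        expected_F = (ss_b / 2) / (ss_w / 6)
        res = anova_oneway(groups)
        assert res.F == pytest.approx(expected_F, rel=1e-12)
        assert res.partial_eta2 == pytest.approx(ss_b / (ss_b + ss_w), rel=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_two_group_f_equals_squared_t(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.7, 1, 12)
        res = anova_oneway({"a": a, "b": b})
        t, _ = sst.ttest_ind(a, b)  # pooled-variance t
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_eta2_grows_with_separation(self, rng):
        base = rng.normal(0, 1, 20)
        small = anova_oneway({"a": base, "b": base + 0.5})
        large = anova_oneway({"a": base, "b": base + 2.0})
        assert 0 <= small.partial_eta2 < large.partial_eta2 <= 1

    def test_power_matches_noncentral_f_closed_form(self):
        res = anova_oneway(
            {"a": [1.0, 2, 3, 4], "b": [2.0, 3, 4, 5], "c": [4.0, 5, 6, 7]}
        )
        lam = 12 * res.partial_eta2 / (1 - res.partial_eta2)
        fcrit = sst.f.isf(0.05, 2, 9)
        assert res.power == pytest.approx(sst.ncf.sf(fcrit, 2, 9, lam), rel=1e-12)

    def test_missing_values_dropped_per_measure(self):
        res = anova_oneway({"a": [1, 2, np.nan], "b": [2, 3, 4], "c": [3, 4, 5]})
        assert res.group_ns == {"a": 2, "b": 3, "c": 3}
        assert res.df_within == 5  # N - k = 8 - 3


class TestTukey:
    def test_identical_groups_not_significant(self):
        res = tukey_hsd({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        assert res.mean_diffs[0] == pytest.approx(0.0)
        assert res.p_adjusted[0] > 0.9

    def test_only_separated_group_flagged(self, rng):
        a = rng.normal(0, 0.5, 12)
        b = rng.normal(0, 0.5, 12)
        c = rng.normal(8, 0.5, 12)  # far beyond within-group SD
        res = tukey_hsd({"a": a, "b": b, "c": c})
        flags = dict(zip(res.pairs, res.significant))
        assert not flags[("a", "b")]
        assert flags[("a", "c")] and flags[("b", "c")]

    def test_matches_statsmodels_reference(self, rng):
        """Dual-route check against the statsmodels Tukey implementation."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {g: rng.normal(i, 1, 10) for i, g in enumerate("abc")}
        ours = tukey_hsd(groups)
        data = np.concatenate(list(groups.values()))
        labels = sum(([g] * 10 for g in groups), [])
        ref = pairwise_tukeyhsd(data, labels)
        assert np.allclose(np.sort(ours.p_adjusted), np.sort(ref.pvalues), atol=1e-6)

    def test_pair_count(self, rng):
        res = tukey_hsd({g: rng.normal(size=5) for g in "abcd"})
        assert len(res.pairs) == 6  # k(k-1)/2


class TestWilcoxon:
    def test_exact_p_matches_full_sign_enumeration(self):
        """n=12, all shifts +1: compare with literal 2^12 enumeration."""
        pre = np.arange(12, dtype=float)
        post = pre + 1.0
        res = wilcoxon_signed_rank(pre, post)
        ranks = sst.rankdata(np.abs(post - pre))
        w_obs = ranks.sum()
        count_ge = count_le = 0
        for signs in product([0, 1], repeat=12):
            w = sum(r for s, r in zip(signs, ranks) if s)
            count_ge += w >= w_obs
            count_le += w <= w_obs
        p_exact = min(1.0, 2.0 * min(count_ge, count_le) / 2**12)
        assert res.method == "exact"
        assert res.p == pytest.approx(p_exact, rel=1e-12)
        assert res.statistic == pytest.approx(w_obs)

    def test_symmetric_differences_near_null(self):
        pre = np.zeros(10)
        post = np.array([1.0, -1.0] * 5)
        res = wilcoxon_signed_rank(pre, post)
        assert res.p > 0.9

    def test_pair_order_invariance(self, rng):
        pre = rng.normal(size=14)
        post = pre + rng.normal(0.3, 1.0, 14)
        a = wilcoxon_signed_rank(pre, post)
        perm = rng.permutation(14)
        b = wilcoxon_signed_rank(pre[perm], post[perm])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_zero_differences_excluded_and_counted(self):
        pre = np.array([1.0, 2, 3, 4, 5, 6, 7])
        post = np.array([1.0, 3, 4, 5, 6, 7, 8])
        res = wilcoxon_signed_rank(pre, post)
        assert res.n_zero_diffs == 1
        assert res.n_pairs == 6

    def test_large_n_uses_normal_approximation(self, rng):
        pre = rng.normal(size=40)
        post = pre + rng.normal(0.5, 1, 40)
        res = wilcoxon_signed_rank(pre, post)
        ref = sst.wilcoxon(post - pre, method="approx", correction=False)
        assert res.method == "normal"
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])


class TestRegression:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        res = linear_regression(2 * x + 1, x)
        assert res.slopes[0] == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.adjusted_r2 == pytest.approx(1.0)

    def test_null_slope_type_one_rate(self, rng):
        """F-test at alpha=0.05 rejects ~5% of independent-data fits."""
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.normal(size=33)
            y = rng.normal(size=33)
            hits += linear_regression(y, x).p < 0.05
        lo, hi = sst.binom.ppf([0.005, 0.995], n_rep, 0.05)
        assert lo <= hits <= hi

    def test_adjusted_r2_below_r2(self, rng):
        x = rng.normal(size=(30, 2))
        y = x @ [1.0, -0.5] + rng.normal(size=30)
        res = linear_regression(y, x)
        assert res.adjusted_r2 <= res.r2
        assert (res.df_model, res.df_resid) == (2, 27)

    def test_collinear_design_rejected(self):
        x = np.ones((10, 2))
        with pytest.raises(ValueError, match="collinear"):
            linear_regression(np.arange(10.0), x)


class TestBonferroni:
    def test_single_test_unchanged(self):
        assert adjust_pvalues([0.04], n_tests=1)[0] == pytest.approx(0.04)

    def test_qualitative_reversal_at_four_tests(self):
        # p = 0.025 uncorrected crosses alpha = 0.05 after m = 4 correction
        adj = adjust_pvalues([0.025], n_tests=4)[0]
        assert adj == pytest.approx(0.1)
        assert adj > 0.05

    def test_capped_at_one(self):
        assert np.all(adjust_pvalues([1.0, 0.9], n_tests=5) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="p-values"):
            adjust_pvalues([1.2], n_tests=2)
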