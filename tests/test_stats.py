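"""Statistical toolkit vs closed-form and reference-library oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spatialtme.stats import (kaplan_meier, km_survival_at, log_rank,
                              normalized_frequencies, p_stars,
                              pearson_correlation, summarize_tests,
                              tissue_nlr, two_way_anova, unpaired_t_test)


class TestNormalizedFrequencies:
    def test_known_fractions(self):
        counts = pd.DataFrame({"a": [2], "b": [3], "c": [5]}, index=["s1"])
        freq = normalized_frequencies(counts)
        assert list(freq.loc["s1"]) == [0.2, 0.3, 0.5]

    def test_single_category(self):
        freq = normalized_frequencies(pd.DataFrame({"a": [7]}, index=["s1"]))
        assert freq.at["s1", "a"] == 1.0

    def test_matches_hand_division(self, rng):
        counts = pd.DataFrame(rng.integers(1, 50, (5, 4)))
        freq = normalized_frequencies(counts)
        for i in counts.index:
            total = counts.loc[i].sum()
            for j in counts.columns:
                assert freq.at[i, j] == counts.at[i, j] / total

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalized_frequencies(pd.DataFrame({"a": [0], "b": [0]}, index=["s"]))


class TestTissueNlr:
    def test_known_ratio(self):
        assert tissue_nlr(30, 10, 5) == 2.0

    def test_zero_neutrophils(self):
        assert tissue_nlr(0, 3, 4) == 0.0

    def test_exact_rational(self):
        # ratio computed via Fraction: correctly rounded for any counts
        assert tissue_nlr(1, 2, 1) == 1 / 3
        assert tissue_nlr(10, 3, 4) == 10 / 7

    def test_zero_lymphocytes_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(tissue_nlr(5, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            tissue_nlr(-1, 2, 3)

    def test_nt_exceeds_it_on_planted_cohort(self, analysis):
        tn = analysis.tnlr
        assert (tn.loc[tn["group"] == "NT", "tnlr"].mean()
                > tn.loc[tn["group"] == "IT", "tnlr"].mean())


class TestUnpairedTTest:
    def test_identical_samples(self):
        r = unpaired_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert r.statistic == 0.0 and r.pvalue == 1.0

    def test_large_separation(self):
        r = unpaired_t_test([1.0, 2, 3], [1001.0, 1002, 1003])
        assert r.pvalue < 0.001

    @pytest.mark.parametrize("variant,equal_var", [("welch", False),
                                                   ("student", True)])
    def test_matches_scipy(self, rng, variant, equal_var):
        for _ in range(25):
            x = rng.normal(0, 1, rng.integers(3, 12))
            y = rng.normal(0.3, 1.7, rng.integers(3, 12))
            mine = unpaired_t_test(x, y, variant=variant)
            ref = sps.ttest_ind(x, y, equal_var=equal_var)
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
            assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-12)
            assert mine.df == pytest.approx(ref.df, abs=1e-12)

    def test_zero_variance_degenerate(self):
        r = unpaired_t_test([2.0, 2, 2], [2.0, 2, 2])
        assert r.degenerate and r.pvalue == 1.0
        r2 = unpaired_t_test([2.0, 2, 2], [3.0, 3, 3])
        assert r2.degenerate and r2.pvalue == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([1.0], [1.0, 2.0])


class TestTwoWayAnova:
    @staticmethod
    def balanced_layout(rng, reps=3):
        a = np.repeat(["a1", "a2", "a3"], 2 * reps)
        b = np.tile(np.repeat(["b1", "b2"], reps), 3)
        y = rng.normal(0, 1, len(a)) + (a == "a2") * 0.5 + (b == "b2") * 0.3
        return y, a, b

    def test_all_equal_values(self):
        y = np.ones(12)
        a = np.repeat(["a1", "a2"], 6)
        b = np.tile(np.repeat(["b1", "b2"], 3), 2)
        res = two_way_anova(y, a, b)
        effects = res.table.drop(index="Residual")
        assert (effects["F"] == 0).all()
        assert (effects["pvalue"] == 1.0).all()

    def test_balanced_decomposition_identity(self, rng):
        y, a, b = self.balanced_layout(rng)
        res = two_way_anova(y, a, b)
        t = res.table
        ss_total = ((y - y.mean()) ** 2).sum()
        assert t["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-10)

    def test_matches_statsmodels_type2(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        y, a, b = self.balanced_layout(rng)
        # make it unbalanced by dropping observations
        keep = np.ones(len(y), bool)
        keep[[0, 7, 13]] = False
        df = pd.DataFrame({"y": y[keep], "a": a[keep], "b": b[keep]})
        ref = sm.stats.anova_lm(ols("y ~ C(a) * C(b)", df).fit(), typ=2)
        mine = two_way_anova(df["y"], df["a"], df["b"]).table
        for effect, row in (("factor_a", "C(a)"), ("factor_b", "C(b)"),
                            ("interaction", "C(a):C(b)")):
            assert mine.at[effect, "sum_sq"] == pytest.approx(
                ref.at[row, "sum_sq"], rel=1e-10)
            assert mine.at[effect, "F"] == pytest.approx(ref.at[row, "F"], rel=1e-10)
            assert mine.at[effect, "pvalue"] == pytest.approx(
                ref.at[row, "PR(>F)"], abs=1e-10)

    def test_single_replicate_drops_interaction(self, rng):
        a = np.repeat(["a1", "a2"], 2)
        b = np.tile(["b1", "b2"], 2)
        y = rng.normal(0, 1, 4)
        res = two_way_anova(y, a, b)
        assert "interaction" not in res.table.index

    def test_single_level_factor_rejected(self, rng):
        with pytest.raises(ValueError):
            two_way_anova(rng.normal(0, 1, 4), ["a"] * 4, ["b1", "b2"] * 2)


class TestPearson:
    def test_perfect_positive_affine(self):
        x = np.arange(10.0)
        r = pearson_correlation(x, 2 * x + 1)
        assert r.r == 1.0 and r.pvalue == 0.0

    def test_perfect_negative(self):
        x = np.arange(5.0)
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0, abs=1e-14)

    def test_matches_scipy(self, rng):
        x = rng.normal(0, 1, 20)
        y = 0.5 * x + rng.normal(0, 1, 20)
        mine = pearson_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert mine.r == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 15)
        y = rng.normal(0, 1, 15)
        base = pearson_correlation(x, y).r
        assert pearson_correlation(3 * x + 7, y).r == pytest.approx(base, abs=1e-12)
        assert pearson_correlation(x, 0.1 * y - 2).r == pytest.approx(base, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1, 1], [1.0, 2, 3])


class TestKaplanMeier:
    def test_four_events_no_censoring(self):
        km = kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        np.testing.assert_allclose(km["survival"], [0.75, 0.5, 0.25, 0.0])

    def test_hand_computed_with_censoring(self):
        # events at 1 and 3, censored at 2:
        # S(1) = 2/3; censoring at 2 leaves S unchanged; S(3) = 2/3 * (1-1/1) = 0
        km = kaplan_meier([1, 2, 3], [1, 0, 1])
        assert km_survival_at(km, 0.5) == 1.0
        assert km_survival_at(km, 1) == pytest.approx(2 / 3)
        assert km_survival_at(km, 2.5) == pytest.approx(2 / 3)
        assert km_survival_at(km, 3) == 0.0

    def test_no_censoring_equals_empirical_survivor(self, rng):
        times = rng.exponential(10, 40).round(1) + 0.1
        km = kaplan_meier(times, np.ones(40, dtype=int))
        for t in np.unique(times):
            assert km_survival_at(km, t) == pytest.approx((times > t).mean(),
                                                          abs=1e-12)

    def test_monotone_nonincreasing(self, rng):
        times = rng.exponential(5, 30) + 0.01
        events = rng.integers(0, 2, 30)
        if events.sum() == 0:
            events[0] = 1
        km = kaplan_meier(times, events)
        assert (np.diff(km["survival"]) <= 1e-15).all()

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        times = rng.exponential(10, 50) + 0.1
        events = rng.integers(0, 2, 50)
        events[0] = 1
        km = kaplan_meier(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in km["time"]:
            assert km_survival_at(km, t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10)


class TestLogRank:
    def test_identical_groups_zero_chi2(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 1, 1, 1, 1]
        groups = ["a", "a", "a", "b", "b", "b"]
        r = log_rank(times, events, groups)
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.pvalue == pytest.approx(1.0)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test
        t1 = rng.exponential(5, 25) + 0.1
        t2 = rng.exponential(12, 25) + 0.1
        e1 = rng.integers(0, 2, 25)
        e2 = rng.integers(0, 2, 25)
        e1[0] = 1
        times = np.r_[t1, t2]
        events = np.r_[e1, e2]
        groups = np.array(["a"] * 25 + ["b"] * 25)
        mine = log_rank(times, events, groups)
        ref = logrank_test(t1, t2, e1, e2)
        assert mine.chi2 == pytest.approx(ref.test_statistic, rel=1e-10)
        assert mine.pvalue == pytest.approx(ref.p_value, abs=1e-10)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            log_rank([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])


class TestReporting:
    def test_star_thresholds(self):
        assert p_stars(0.0005) == "***"
        assert p_stars(0.005) == "**"
        assert p_stars(0.05) == "*"
        assert p_stars(0.2) == "ns"

    def test_summarize_tests_table(self):
        r = unpaired_t_test([1.0, 2, 3], [4.0, 5, 6])
        c = pearson_correlation([1.0, 2, 3, 4], [1.1, 2.2, 2.9, 4.1])
        out = summarize_tests([
            {"test": "t", "comparison": "x-y", "result": r},
            {"test": "pearson", "comparison": "x~y", "result": c}])
        assert list(out.columns) == ["test", "comparison", "statistic", "df",
                                     "pvalue", "stars"]
        assert len(out) == 2
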