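"""Statistical layer: Wilson CIs, Yates chi-square, ANOVA/Tukey, KW, drivers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from urbanfrail.stats import (
    StatsError,
    anova_tukey,
    chisq_yates,
    cluster_distribution_table,
    compare_by_frailty,
    kruskal_wallis,
    sociodemographic_table,
    wilson_ci,
)


class TestWilson:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (64, 251, (25.5, 20.5, 31.2)),
            (10, 64, (15.6, 8.7, 26.4)),
            (16, 64, (25.0, 16.0, 36.8)),
            (19, 187, (10.2, 6.6, 15.3)),
        ],
    )
    def test_reproduces_published_cohort_intervals(self, k, n, expected):
        assert wilson_ci(k, n).as_percent(1) == expected

    def test_zero_successes_boundary(self):
        ci = wilson_ci(0, 10)
        assert ci.lo == 0.0 and ci.p_hat == 0.0 and ci.hi > 0

    def test_ordering_invariant(self):
        ci = wilson_ci(5, 30)
        assert 0 <= ci.lo <= ci.p_hat <= ci.hi <= 1

    def test_matches_statsmodels_wilson(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(3, 17), (40, 100), (99, 100)]:
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            ci = wilson_ci(k, n)
            assert ci.lo == pytest.approx(lo, abs=1e-10)
            assert ci.hi == pytest.approx(hi, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(StatsError):
            wilson_ci(1, 0)
        with pytest.raises(StatsError):
            wilson_ci(5, 3)


class TestChisqYates:
    def test_no_association(self):
        stat, p = chisq_yates([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_matches_closed_form_arithmetic(self):
        # N=50, |ad-bc| = |400-25| = 375, corrected 350
        # chi2 = 50*350^2 / (25*25*25*25)
        stat, p = chisq_yates([[20, 5], [5, 20]])
        assert stat == pytest.approx(50 * 350**2 / 25**4)
        assert p == pytest.approx(sps.chi2.sf(stat, 1))

    def test_matches_scipy_continuity_correction(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            t = rng.integers(1, 40, (2, 2))
            stat, p = chisq_yates(t)
            ref = sps.chi2_contingency(t, correction=True)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_never_exceeds_uncorrected(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            t = rng.integers(1, 40, (2, 2))
            stat, _ = chisq_yates(t)
            un = sps.chi2_contingency(t, correction=False).statistic
            assert stat <= un + 1e-12

    def test_correction_floor_keeps_statistic_nonnegative(self):
        stat, p = chisq_yates([[1, 2], [2, 1]])  # |ad-bc|=3 < N/2=3 -> floored
        assert stat == 0.0 and p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError):
            chisq_yates([[0, 0], [5, 5]])


class TestAnovaTukey:
    def test_textbook_three_group_table(self):
        """Hand-computed one-way ANOVA on a 3x5 fixture.

        groups: (1,2,3,4,5), (2,3,4,5,6), (4,5,6,7,8); grand mean 4.333...
        SSB = 5*[(3-13/3)^2 + (4-13/3)^2 + (6-13/3)^2] = 23.333...
        SSW = 3*10 = 30; F = (SSB/2)/(SSW/12) = 11.666../2.5 = 4.666...
        """
        g = [np.array([1, 2, 3, 4, 5]), np.array([2, 3, 4, 5, 6]),
             np.array([4, 5, 6, 7, 8])]
        res = anova_tukey(g, ["a", "b", "c"])
        assert res.statistic == pytest.approx(14 / 3, abs=1e-6)
        assert res.p_value == pytest.approx(sps.f.sf(14 / 3, 2, 12), abs=1e-9)
        assert set(res.pairwise) == {("a", "b"), ("a", "c"), ("b", "c")}
        assert all(0 <= p <= 1 for p in res.pairwise.values())

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        res = anova_tukey([a, b])
        t = sps.ttest_ind(a, b).statistic
        assert res.statistic == pytest.approx(t**2, rel=1e-10)

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            g = [rng.normal(0, 1, 10) for _ in range(3)]
            if anova_tukey(g).p_value < 0.05:
                rejections += 1
        assert 0.03 < rejections / reps < 0.07

    def test_group_size_validation(self):
        with pytest.raises(StatsError):
            anova_tukey([np.array([1.0]), np.array([1.0, 2.0])])

    def test_se_is_sd_over_sqrt_n(self):
        g = [np.array([1.0, 2.0, 3.0, 4.0]), np.array([2.0, 4.0, 6.0, 8.0])]
        res = anova_tukey(g)
        assert res.ses[0] == pytest.approx(np.std(g[0], ddof=1) / 2)


class TestKruskalWallis:
    def test_identical_groups_convention(self):
        h, p = kruskal_wallis([np.ones(5), np.ones(4)])
        assert h == 0.0 and p == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        g = [rng.normal(0, 1, 8) for _ in range(3)]
        h1, _ = kruskal_wallis(g)
        h2, _ = kruskal_wallis([np.exp(x) for x in g])
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_manual_ranking_oracle_with_ties(self):
        """H recomputed by hand on a 12-value fixture with ties."""
        g = [np.array([1.0, 2.0, 2.0, 3.0]), np.array([2.0, 4.0, 5.0, 5.0]),
             np.array([5.0, 6.0, 7.0, 8.0])]
        h, p = kruskal_wallis(g)
        allv = np.concatenate(g)
        order = sps.rankdata(allv)  # mean ranks for ties
        n = len(allv)
        ranks = [order[:4], order[4:8], order[8:]]
        h_manual = 12 / (n * (n + 1)) * sum(
            len(r) * (r.mean() - (n + 1) / 2) ** 2 for r in ranks
        )
        # tie correction
        _, counts = np.unique(allv, return_counts=True)
        h_manual /= 1 - (counts**3 - counts).sum() / (n**3 - n)
        assert h == pytest.approx(h_manual, rel=1e-12)


class TestCompareByFrailty:
    def test_planted_effect_sign(self, exposure):
        res = compare_by_frailty(exposure, "dist_emergency_health_centers_m")
        means = dict(zip(res.groups, res.means))
        assert means["frail"] == min(means.values())

    def test_mean_se_match_direct_computation(self, exposure):
        res = compare_by_frailty(exposure, "density")
        for g, n, m, se in zip(res.groups, res.ns, res.means, res.ses):
            vals = exposure.loc[exposure["category"] == g, "density"]
            assert n == len(vals)
            assert m == pytest.approx(vals.mean())
            assert se == pytest.approx(vals.std(ddof=1) / np.sqrt(len(vals)))

    def test_policy_forcing(self, exposure):
        a = compare_by_frailty(exposure, "density", policy="anova")
        k = compare_by_frailty(exposure, "density", policy="kw")
        assert a.test == "anova" and a.pairwise
        assert k.test == "kruskal-wallis" and not k.pairwise

    def test_absent_category_warns_and_compares_rest(self, exposure):
        sub = exposure[exposure["category"] != "frail"]
        res = compare_by_frailty(sub, "density")
        assert res.groups == ["robust", "prefrail"]

    def test_single_category_rejected(self, exposure):
        sub = exposure[exposure["category"] == "frail"]
        with pytest.raises(StatsError):
            compare_by_frailty(sub, "density")


class TestClusterDistribution:
    def test_columns_sum_to_100(self, exposure):
        table = cluster_distribution_table(exposure)
        for cat in ("robust", "prefrail", "frail"):
            assert table[f"{cat}_pct"].sum() == pytest.approx(100, abs=0.3)

    def test_single_cluster_city_gives_100_percent(self):
        e = pd.DataFrame(
            {
                "cluster_id": [1] * 9,
                "category": ["robust"] * 3 + ["prefrail"] * 3 + ["frail"] * 3,
            }
        )
        table = cluster_distribution_table(e)
        assert len(table) == 1
        for cat in ("robust", "prefrail", "frail"):
            assert table[f"{cat}_pct"].iloc[0] == 100.0

    def test_percentages_match_hand_tallies(self):
        # 12 people, 2 clusters: robust 2/4 each... laid out by hand
        e = pd.DataFrame(
            {
                "cluster_id": [1, 1, 2, 2, 1, 1, 1, 2, 2, 2, 1, 2],
                "category": ["robust"] * 4 + ["prefrail"] * 6 + ["frail"] * 2,
            }
        )
        table = cluster_distribution_table(e).set_index("cluster")
        assert table.loc[1, "robust_pct"] == 50.0  # 2/4
        assert table.loc[1, "prefrail_pct"] == pytest.approx(50.0)  # 3/6
        assert table.loc[1, "frail_pct"] == 50.0  # 1/2
        assert table.loc[2, "robust_pct"] == 50.0

    def test_unassigned_excluded(self, exposure):
        e = exposure.copy()
        e.loc[e.index[:5], "cluster_id"] = -1
        table = cluster_distribution_table(e)
        assert set(table["cluster"]) == set(range(1, 7))


class TestSociodemographicTable:
    def test_structure_and_gender_ci(self, exposure, cohort):
        t = sociodemographic_table(exposure, cohort.table)
        gender = t[t["variable"] == "gender_female"]["value"].iloc[0]
        n_women = int((cohort.table["sex"] == "female").sum())
        expect = wilson_ci(n_women, len(cohort.table)).as_percent()
        assert gender == f"{expect[0]} ({expect[1]}-{expect[2]})"
        assert {"age", "bmi"} <= set(t["variable"])
        assert any(v.startswith("cluster_") for v in t["variable"])
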