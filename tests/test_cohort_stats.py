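import numpy as np
import pytest
from scipy import stats

from cortexmicro.cohort_stats import (
    anova_report,
    brown_forsythe,
    describe_groups,
    games_howell_posthoc,
    levene_test,
    lsd_posthoc,
    one_way_anova,
    pearson_r,
    welch_anova,
)

TOY = ([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0])
HETERO = ([10.0, 11.0, 9.0, 10.5, 9.5, 10.2],
          [12.0, 18.0, 6.0, 15.0, 9.0, 13.0],
          [20.0, 21.5, 19.0, 20.5, 19.5, 21.0, 20.2, 19.8])


class TestOneWayAnova:
    def test_hand_computed_sums_of_squares(self):
        # group means 2,5,8; SSB=54 (df 2) -> MSB=27; SSW=6 (df 6) -> MSW=1
        f, df, p = one_way_anova(TOY)
        assert f == pytest.approx(27.0)
        assert df == (2, 6)
        assert p == pytest.approx(stats.f.sf(27, 2, 6))

    def test_identical_group_means_give_zero_f(self):
        f, _, p = one_way_anova(([1, 2, 3], [2, 2, 2], [3, 2, 1]))
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_groups_equals_squared_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        f, _, p_f = one_way_anova([a, b])
        t, p_t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_shift_and_scale_invariance(self, rng):
        gs = [rng.normal(0, 1, 10) for _ in range(3)]
        f0, _, _ = one_way_anova(gs)
        f1, _, _ = one_way_anova([g + 100 for g in gs])
        f2, _, _ = one_way_anova([g * 3.5 for g in gs])
        assert f1 == pytest.approx(f0)
        assert f2 == pytest.approx(f0)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova(([1.0], [2.0, 3.0]))


class TestLevene:
    def test_identical_groups_give_zero(self):
        w, _ = levene_test(([1, 2, 3], [1, 2, 3]))
        assert w == pytest.approx(0.0)

    def test_null_rejection_rate_near_alpha(self, rng):
        rejections = 0
        reps = 1000
        for _ in range(reps):
            gs = [rng.normal(0, 1, 15) for _ in range(3)]
            _, p = levene_test(gs)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_power_against_ninefold_variance_ratio(self, rng):
        rejections = 0
        reps = 200
        for _ in range(reps):
            gs = [rng.normal(0, 3, 30), rng.normal(0, 1, 30), rng.normal(0, 1, 30)]
            _, p = levene_test(gs)
            rejections += p < 0.05
        assert rejections / reps > 0.8

    def test_constant_groups_flagged(self):
        with pytest.raises(ValueError):
            levene_test(([2.0, 2.0], [2.0, 2.0]))


class TestLsdPosthoc:
    def test_textbook_formula_on_toy(self):
        # MSE=1 (df 6); pair (0,1): diff=-3, se=sqrt(1*(2/3))
        table = lsd_posthoc(TOY)
        row = table.iloc[0]
        se = np.sqrt(2 / 3)
        assert row["mean_diff"] == pytest.approx(-3.0)
        assert row["se"] == pytest.approx(se)
        assert row["p"] == pytest.approx(2 * stats.t.sf(3.0 / se, 6))

    def test_identical_pair_not_significant(self):
        table = lsd_posthoc(([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 10.0, 11.0]))
        assert table.iloc[0]["p"] == pytest.approx(1.0)

    def test_symmetric_in_pair_order(self):
        t1 = lsd_posthoc(TOY)
        t2 = lsd_posthoc(TOY[::-1])
        assert t1.iloc[0]["p"] == pytest.approx(t2.iloc[0]["p"])
        assert t1.iloc[0]["mean_diff"] == pytest.approx(-t2.iloc[-1]["mean_diff"])


class TestGamesHowell:
    def test_matches_pingouin_on_heteroscedastic_toy(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        table = games_howell_posthoc(HETERO, labels=["a", "b", "c"])
        long = pd.DataFrame(
            {"y": np.concatenate(HETERO),
             "g": np.repeat(["a", "b", "c"], [len(g) for g in HETERO])}
        )
        ref = pg.pairwise_gameshowell(data=long, dv="y", between="g")
        for _, row in table.iterrows():
            match = ref[(ref["A"] == row["group1"]) & (ref["B"] == row["group2"])]
            assert abs(row["mean_diff"]) == pytest.approx(
                abs(match["diff"].iloc[0]), rel=1e-9
            )
            assert row["df"] == pytest.approx(match["df"].iloc[0], rel=1e-9)
            assert row["p"] == pytest.approx(match["pval"].iloc[0], abs=1e-6)

    def test_welch_df_within_known_bounds(self):
        table = games_howell_posthoc(HETERO)
        ns = [len(g) for g in HETERO]
        for _, row in table.iterrows():
            i = ["g0", "g1", "g2"].index(row["group1"])
            j = ["g0", "g1", "g2"].index(row["group2"])
            assert min(ns[i], ns[j]) - 1 <= row["df"] <= ns[i] + ns[j] - 2

    def test_equal_groups_not_significant(self):
        table = games_howell_posthoc(([1, 2, 3, 4], [1, 2, 3, 4], [1, 2, 3, 4]))
        assert (table["p"] > 0.9).all()


class TestRobustOmnibus:
    def test_welch_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        f, df1, df2, p = welch_anova(HETERO)
        long = pd.DataFrame(
            {"y": np.concatenate(HETERO),
             "g": np.repeat(["a", "b", "c"], [len(g) for g in HETERO])}
        )
        ref = pg.welch_anova(data=long, dv="y", between="g")
        assert f == pytest.approx(ref["F"].iloc[0], rel=1e-9)
        assert df2 == pytest.approx(ref["ddof2"].iloc[0], rel=1e-9)
        assert p == pytest.approx(ref["p_unc"].iloc[0], abs=1e-9)

    def test_brown_forsythe_textbook_formulas(self):
        # independent recomputation from definitions
        gs = [np.asarray(g, dtype=float) for g in HETERO]
        n = np.array([g.size for g in gs])
        m = np.array([g.mean() for g in gs])
        v = np.array([g.var(ddof=1) for g in gs])
        grand = np.concatenate(gs).mean()
        num = (n * (m - grand) ** 2).sum()
        den_terms = (1 - n / n.sum()) * v
        expected_f = num / den_terms.sum()
        c = den_terms / den_terms.sum()
        expected_df2 = 1 / (c**2 / (n - 1)).sum()
        f, df1, df2, p = brown_forsythe(HETERO)
        assert f == pytest.approx(expected_f)
        assert df1 == 2
        assert df2 == pytest.approx(expected_df2)

    def test_equal_groups_give_zero_statistics(self):
        same = ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert welch_anova(same)[0] == pytest.approx(0.0)
        assert brown_forsythe(same)[0] == pytest.approx(0.0)

    def test_homoscedastic_case_welch_tracks_classical_f(self, rng):
        gs = [rng.normal(0.3 * i, 1, 200) for i in range(3)]
        f_classic, _, _ = one_way_anova(gs)
        f_welch, *_ = welch_anova(gs)
        assert abs(f_welch - f_classic) / f_classic < 0.05

    def test_null_type_one_error_all_tests(self, rng):
        # homoscedastic normal null: each test's rejection rate near 0.05
        reps = 2000
        rej = np.zeros(3)
        for _ in range(reps):
            gs = [rng.normal(0, 1, 10) for _ in range(3)]
            rej[0] += one_way_anova(gs)[2] < 0.05
            rej[1] += welch_anova(gs)[3] < 0.05
            rej[2] += brown_forsythe(gs)[3] < 0.05
        rates = rej / reps
        assert np.all(rates >= 0.03) and np.all(rates <= 0.07), rates


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_formula_on_three_points(self):
        x, y = [1.0, 2.0, 4.0], [1.0, 3.0, 4.0]
        r, _ = pearson_r(x, y)
        xm, ym = np.mean(x), np.mean(y)
        expected = (np.sum((x - xm) * (y - ym))
                    / np.sqrt(np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2)))
        assert r == pytest.approx(expected)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestReport:
    def test_heteroscedastic_variable_switches_to_games_howell(self):
        report = anova_report(HETERO, variable="y")
        assert report.levene_p < 0.05
        assert report.posthoc_method == "Games-Howell"

    def test_report_serializes(self):
        d = anova_report(TOY, variable="toy").to_dict()
        assert d["F"] == 27.0
        assert d["df1"] == 2 and d["df2"] == 6

    def test_describe_groups(self, study_cohort):
        participants, _ = study_cohort
        desc = describe_groups(participants, "gidyq_mean",
                               group_order=["cis_boy", "gd_afab", "cis_girl"])
        assert list(desc["n"]) == [14, 15, 17]
        # GD group well below the cis groups, mirroring the screening split
        assert desc.loc[1, "mean"] < 3.0 < desc.loc[0, "mean"]
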