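import numpy as np
import pytest
import scipy.stats

from _oracles import exact_mwu_p
from eegarousal.stats import (
    chi_square_2x2,
    ids_severity_band,
    levene_test,
    mann_whitney,
    one_way_anova,
    roc_auc,
    screening_metrics,
    screening_metrics_from_counts,
    two_way_anova,
)


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        res = one_way_anova(values, ["a"] * 3 + ["b"] * 3)
        assert res.F == 0.0
        assert res.eta_sq_partial == 0.0

    def test_f_equals_squared_t(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0.4, 1, 30)
        res = one_way_anova(np.r_[x, y], ["a"] * 25 + ["b"] * 30)
        t = scipy.stats.ttest_ind(x, y)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p == pytest.approx(t.pvalue, rel=1e-10)
        assert res.df_between == 1 and res.df_within == 53

    def test_eta_formula(self, rng):
        values = rng.normal(size=40)
        groups = ["a"] * 20 + ["b"] * 20
        res = one_way_anova(values, groups)
        # partial eta^2 for one factor: F*df_b / (F*df_b + df_w)
        expected = res.F * res.df_between / (res.F * res.df_between + res.df_within)
        assert res.eta_sq_partial == pytest.approx(expected, rel=1e-12)

    def test_degenerate_group_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            one_way_anova([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_power_at_printed_group_parameters(self):
        # 19 @ 20.6 +/- 7.3 vs 41 @ 12.6 +/- 6.2: d ~ 1.2, power >> 0.8
        rng = np.random.default_rng(5)
        groups = ["h"] * 19 + ["n"] * 41
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            vals = np.r_[rng.normal(20.6, 7.3, 19), rng.normal(12.6, 6.2, 41)]
            if one_way_anova(vals, groups).p < 0.05:
                hits += 1
        assert hits / n_rep >= 0.80


class TestTwoWayAnova:
    def test_null_calibration_balanced(self):
        rng = np.random.default_rng(11)
        group = ["a"] * 20 + ["b"] * 20
        gender = (["f"] * 10 + ["m"] * 10) * 2
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            res = two_way_anova(rng.normal(size=40), group, gender)
            if res["group"].p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_group_effect_dominates_gender_null(self):
        rng = np.random.default_rng(13)
        group = np.array(["h"] * 19 + ["n"] * 41)
        gender = np.array((["f", "m"] * 30))[:60]
        wins = 0
        n_rep = 120
        for _ in range(n_rep):
            vals = np.where(group == "h", 20.6, 12.6) + rng.normal(0, 6.6, 60)
            res = two_way_anova(vals, group, gender)
            if res["group"].p < res["gender"].p:
                wins += 1
        assert wins / n_rep >= 0.95

    def test_single_observation_cell_raises(self):
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(
                [1.0, 2, 3, 4, 5, 6, 7],
                ["a", "a", "a", "a", "b", "b", "b"],
                ["f", "f", "m", "m", "f", "f", "m"],
            )

    def test_effects_reported(self, rng):
        vals = rng.normal(size=40)
        res = two_way_anova(vals, ["a", "b"] * 20, ["f", "f", "m", "m"] * 10)
        assert set(res) == {"group", "gender", "interaction"}
        for effect in res.values():
            assert 0 <= effect.p <= 1
            assert 0 <= effect.eta_sq_partial <= 1


class TestLevene:
    def test_identical_groups_zero(self):
        stat, _ = levene_test([1.0, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert stat == pytest.approx(0.0)

    def test_matches_scipy_mean_centre(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=25)
        stat, p = levene_test(np.r_[x, y], ["a"] * 30 + ["b"] * 25)
        ref = scipy.stats.levene(x, y, center="mean")
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_equal_variances_rarely_rejected(self):
        rng = np.random.default_rng(21)
        hits = sum(
            levene_test(rng.normal(size=200), ["a"] * 100 + ["b"] * 100)[1] < 0.05
            for _ in range(200)
        )
        assert hits / 200 <= 0.09

    def test_variance_ratio_nine_detected(self):
        rng = np.random.default_rng(22)
        groups = ["a"] * 50 + ["b"] * 50
        hits = sum(
            levene_test(np.r_[rng.normal(0, 3, 50), rng.normal(0, 1, 50)], groups)[1]
            < 0.05
            for _ in range(100)
        )
        assert hits / 100 >= 0.95


class TestChiSquare:
    def test_printed_gender_table(self):
        stat, df, p = chi_square_2x2([[14, 5], [19, 22]])
        assert round(stat, 2) == 3.92
        assert df == 1
        assert 0.04 < p < 0.06

    def test_uniform_table_zero(self):
        stat, _, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_expected_counts_oracle(self, rng):
        table = rng.integers(1, 40, size=(2, 2))
        stat, _, _ = chi_square_2x2(table)
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        by_hand = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(by_hand, rel=1e-12)

    def test_invariances(self):
        table = np.array([[14, 5], [19, 22]])
        base = chi_square_2x2(table)[0]
        assert chi_square_2x2(table.T)[0] == pytest.approx(base)
        assert chi_square_2x2(table[::-1, ::-1])[0] == pytest.approx(base)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestMannWhitney:
    def test_identical_samples_z_zero(self):
        U, Z, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert Z == pytest.approx(0.0)
        assert U == pytest.approx(8.0)

    def test_complete_separation_u_zero(self):
        U, Z, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert U == 0.0  # U counts x-over-y wins
        assert Z < 0

    def test_small_sample_p_matches_enumeration(self, rng):
        for _ in range(10):
            n1, n2 = int(rng.integers(3, 6)), int(rng.integers(3, 6))
            x = list(np.round(rng.normal(size=n1), 3))
            y = list(np.round(rng.normal(0.5, 1, size=n2), 3))
            _, _, p = mann_whitney(x, y)
            assert p == pytest.approx(exact_mwu_p(x, y), abs=0.01)

    def test_tie_corrected_z(self):
        # heavy ties: sigma must shrink relative to the tie-free formula
        x = [1, 1, 1, 2, 2]
        y = [1, 2, 2, 2, 3]
        U, Z, _ = mann_whitney(x, y)
        n1 = n2 = 5
        mu = n1 * n2 / 2
        sigma_no_tie = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert abs(Z) > abs((U - mu) / sigma_no_tie)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestScreening:
    def test_printed_screen(self):
        m = screening_metrics_from_counts(tp=4, fp=15, tn=41, fn=0)
        assert m.sensitivity == 1.0
        assert round(m.specificity * 100) == 73
        assert round(m.auc_binary, 2) == 0.87
        assert round(m.youden, 1) == 0.7
        assert m.tp + m.fp + m.tn + m.fn == 60

    def test_perfect_test(self):
        m = screening_metrics([True, True, False], [True, True, False])
        assert m.sensitivity == m.specificity == m.auc_binary == m.youden == 1.0

    def test_all_positive_uninformative(self):
        m = screening_metrics([True] * 6, [True, False, False, True, False, False])
        assert m.sensitivity == 1.0 and m.specificity == 0.0
        assert m.youden == 0.0

    def test_count_conservation(self, rng):
        test = rng.random(50) > 0.5
        cond = rng.random(50) > 0.7
        if cond.all() or not cond.any():
            cond[0], cond[1] = True, False
        m = screening_metrics(test, cond)
        assert m.tp + m.fp + m.tn + m.fn == 50
        assert m.auc_binary == pytest.approx((m.sensitivity + m.specificity) / 2)
        assert m.youden == pytest.approx(m.sensitivity + m.specificity - 1)

    def test_no_cases_raises(self):
        with pytest.raises(ValueError):
            screening_metrics([True, False], [False, False])

    def test_roc_auc_matches_rank_formulation(self, rng):
        scores = rng.integers(1, 15, 60).astype(float)
        cond = rng.random(60) > 0.8
        if not cond.any() or cond.all():
            cond[:2] = [True, False]
        auc = roc_auc(scores, cond)
        ref = scipy.stats.mannwhitneyu(scores[cond], scores[~cond]).statistic / (
            cond.sum() * (~cond).sum()
        )
        assert auc == pytest.approx(ref)


class TestSeverityBands:
    @pytest.mark.parametrize(
        "score,band",
        [(0, "none"), (13, "none"), (14, "mild"), (25, "mild"),
         (26, "moderate"), (38, "moderate"), (39, "severe"), (84, "severe")],
    )
    def test_boundaries(self, score, band):
        assert ids_severity_band(score) == band

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            ids_severity_band(85)
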