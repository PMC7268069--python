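import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import editedmrs as em
from editedmrs.stats import (GroupSummary, add_cingulate_rows, anova_from_summary,
                             chi_square_contingency, fit_glm, kruskal_wallis,
                             one_way_anova, tukey_posthoc,
                             variance_and_normality_checks)


def _manual_anova(groups):
    """Textbook between/within decomposition, written independently."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


class TestOneWayAnova:
    def test_identical_means_give_zero_f(self):
        g = [1.0, 2.0, 3.0]
        F, *_ = one_way_anova([g, g, g])
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        gs = [rng.normal(i, 1, 12) for i in range(3)]
        F1, *_ = one_way_anova(gs)
        F2, *_ = one_way_anova([3.5 * g - 2.0 for g in gs])
        assert F2 == pytest.approx(F1, abs=1e-9)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        gs = [rng.normal(0, 1, n) for n in (8, 13, 21)]
        F, dfb, dfw, p = one_way_anova(gs)
        assert F == pytest.approx(_manual_anova(gs), rel=1e-12)
        assert (dfb, dfw) == (2, 39)
        assert p == pytest.approx(sps.f_oneway(*gs).pvalue, rel=1e-9)


class TestAnovaFromSummary:
    def test_equals_raw_anova_on_moment_matched_data(self):
        rng = np.random.default_rng(4)
        gs = [rng.normal(1.5, 0.4, n) for n in (26, 18, 16)]
        F_raw, *_ = one_way_anova(gs)
        summ = [GroupSummary(g.mean(), g.std(ddof=1), len(g)) for g in gs]
        F_sum, *_ = anova_from_summary(summ)
        assert F_sum == pytest.approx(F_raw, abs=1e-9)

    def test_equal_means_zero(self):
        s = [GroupSummary(2.0, 0.3, 10)] * 3
        F, *_ = anova_from_summary(s)
        assert F == 0.0


class TestTukey:
    def test_identical_groups_p_near_one(self):
        g = list(np.arange(10.0))
        out = tukey_posthoc([g, g, [x + 5 for x in g]])
        same = out.query("group_a == 'group0' and group_b == 'group1'")
        assert same.p_adjusted.iloc[0] > 0.99

    def test_large_separation_detected(self):
        rng = np.random.default_rng(5)
        gs = [rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(10, 1, 15)]
        out = tukey_posthoc(gs)
        assert out.query("group_b == 'group2'").p_adjusted.max() < 0.001

    def test_p_ordering_follows_mean_differences(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1.0, 20)
        gs = [base, base + 0.5, base + 2.0]
        out = tukey_posthoc(gs).set_index(["group_a", "group_b"])
        p01 = out.loc[("group0", "group1")].p_adjusted
        p02 = out.loc[("group0", "group2")].p_adjusted
        assert p02 < p01


class TestVarianceNormality:
    def test_levene_location_invariance(self):
        rng = np.random.default_rng(7)
        gs = [rng.normal(0, 1, 20) for _ in range(3)]
        w1 = variance_and_normality_checks(gs)["levene_W"]
        gs2 = [gs[0] + 100.0, gs[1], gs[2]]
        w2 = variance_and_normality_checks(gs2)["levene_W"]
        assert w2 == pytest.approx(w1, rel=1e-9)

    def test_levene_power_against_9x_variance(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(30):
            gs = [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(0, 3, 50)]
            if variance_and_normality_checks(gs)["levene_p"] < 0.01:
                hits += 1
        assert hits >= 27

    def test_constant_group_flagged(self):
        out = variance_and_normality_checks(
            [[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        assert out["degenerate"] == [True, False]
        assert np.isnan(out["shapiro_p"][0])


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        chi2, df, _ = chi_square_contingency([[10, 20], [5, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_2x2_closed_form(self):
        a, b, c, d = 12, 5, 7, 9
        chi2, df, _ = chi_square_contingency([[a, b], [c, d]])
        n = a + b + c + d
        expected = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_contingency([[0, 0], [3, 4]])


class TestKruskal:
    def test_thin_rank_variant(self):
        rng = np.random.default_rng(9)
        gs = [rng.normal(i, 1, 15) for i in range(3)]
        H, df, p = kruskal_wallis(gs)
        assert df == 2 and H > 0 and 0 <= p <= 1


class TestGlm:
    def test_three_by_three_design_dfs(self):
        truth, _ = em.simulate_cohort(em.CohortSimConfig(seed=3),
                                      generate_series=False)
        truth["measure"] = truth.true_gsh_mm
        full = add_cingulate_rows(truth, "measure")
        res = fit_glm(full, "measure")
        dfs = res.effects.set_index("Source").df
        assert dfs["Group"] == 2
        assert dfs["Region"] == 2
        assert dfs["Group x region"] == 4

    def test_injected_group_effect_recovered(self):
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 25
        for _ in range(n_rep):
            rows = []
            for g, (shift, n) in {"NC": (0.5, 26), "MCI": (0.0, 18),
                                  "AD": (0.0, 16)}.items():
                for i in range(n):
                    age = rng.normal(70, 7)
                    sex = rng.choice(["M", "F"])
                    for r in ("ACC", "PCC"):
                        rows.append({"group": g, "region": r, "age": age,
                                     "sex": sex,
                                     "measure": shift + rng.normal(1.8, 0.4)})
            res = fit_glm(pd.DataFrame(rows), "measure")
            p_group = res.effects.set_index("Source").loc["Group", "p"]
            contrast = res.contrasts.query(
                "factor == 'group' and level_a == 'MCI' and level_b == 'NC'")
            if p_group < 0.05 and contrast.estimate.iloc[0] < 0:
                hits += 1
        assert hits >= int(0.95 * n_rep)

    def test_bonferroni_multiplies_by_contrast_count(self):
        rng = np.random.default_rng(11)
        rows = []
        for g in ("NC", "MCI", "AD"):
            for i in range(12):
                rows.append({"group": g, "region": "ACC",
                             "age": rng.normal(70, 7),
                             "sex": rng.choice(["M", "F"]),
                             "measure": rng.normal(1.8, 0.4)})
        res = fit_glm(pd.DataFrame(rows), "measure", include_interaction=False)
        assert (res.contrasts.p_adj <= 1.0).all()
        assert len(res.contrasts.query("factor == 'group'")) == 3
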