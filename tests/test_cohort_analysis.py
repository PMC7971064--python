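"""Group statistics against independent references; report structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nashmri.cohort_analysis import (
    anova_tukey,
    build_report,
    pearson_r,
    welch_t,
)
from nashmri.phantom import build_trajectory
from nashmri.pipeline import CohortDesign, simulate_cohort


class TestWelchT:
    def test_identical_groups(self):
        c = welch_t([1, 2, 3], [1, 2, 3])
        assert c.statistic == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)
        assert not c.significant

    def test_zero_variance_groups_resolved_deterministically(self):
        equal = welch_t([5, 5, 5], [5, 5, 5])
        assert (equal.statistic, equal.p_value) == (0.0, 1.0)
        apart = welch_t([5, 5, 5], [9, 9, 9])
        assert apart.p_value == 0.0 and np.isinf(apart.statistic)

    def test_textbook_pair_matches_reference_implementation(self):
        """Classic two-sample measurement data; scipy is the independent
        reference for both Welch and pooled variants."""
        a = np.array([30.02, 29.99, 30.11, 29.97, 30.01, 29.99])
        b = np.array([29.89, 29.93, 29.72, 29.98, 30.02, 29.98])
        ours = welch_t(a, b)
        ref_t, ref_p = sps.ttest_ind(a, b, equal_var=False)
        assert ours.statistic == pytest.approx(ref_t, abs=1e-6)
        assert ours.p_value == pytest.approx(ref_p, abs=1e-6)
        pooled = welch_t(a, b, equal_var=True)
        ref_t2, _ = sps.ttest_ind(a, b, equal_var=True)
        assert pooled.statistic == pytest.approx(ref_t2, abs=1e-6)

    def test_reports_group_summaries(self):
        c = welch_t([1.0, 2.0, 3.0], [4.0, 6.0], name_a="ctl", name_b="trt")
        assert (c.name_a, c.name_b) == ("ctl", "trt")
        assert c.mean_a == 2.0 and c.n_a == 3
        assert c.sem_a == pytest.approx(1.0 / np.sqrt(3))

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])


class TestAnovaTukey:
    def test_identical_groups_give_zero_f(self):
        res = anova_tukey([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.f_statistic == pytest.approx(0.0)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([[1, 2], [3, 4]])

    def test_tukey_adjusted_p_not_below_unadjusted(self):
        """Over 100 random datasets, each Tukey-adjusted pairwise p is ≥ the
        unadjusted pairwise p computed in the same pooled-variance ANOVA
        frame (MSE pooled over all groups, df = N − k)."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            groups = [rng.normal(rng.uniform(-1, 1), 1.0, size=6)
                      for _ in range(3)]
            res = anova_tukey(groups)
            n = 6
            df = 3 * (n - 1)
            mse = np.mean([np.var(g, ddof=1) for g in groups])
            pairs = [(0, 1), (0, 2), (1, 2)]
            for comp, (i, j) in zip(res.pairwise, pairs):
                t = abs(np.mean(groups[i]) - np.mean(groups[j])) \
                    / np.sqrt(mse * 2 / n)
                p_unadj = 2 * sps.t.sf(t, df)
                assert comp.p_value >= p_unadj - 1e-12

    def test_far_shifted_group_is_significant_everywhere(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 8), rng.normal(0, 1, 8),
                  rng.normal(50, 1, 8)]
        res = anova_tukey(groups, labels=["a", "b", "c"])
        for comp in res.pairwise:
            if "c" in (comp.name_a, comp.name_b):
                assert comp.significant

    def test_matches_scipy_tukey_reference(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 7) for m in (0.0, 0.5, 1.5)]
        res = anova_tukey(groups)
        ref = sps.tukey_hsd(*groups)
        for comp, (i, j) in zip(res.pairwise, [(0, 1), (0, 2), (1, 2)]):
            assert comp.p_value == pytest.approx(ref.pvalue[i, j], abs=1e-6)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_hand_formula_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean())**2)
                            * np.sum((y - y.mean())**2)))
        assert pearson_r(x, y).r == pytest.approx(r_hand, abs=1e-12)

    def test_fisher_ci_brackets_r(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        res = pearson_r(x, y)
        assert res.ci_low < res.r < res.ci_high
        assert -1 <= res.ci_low and res.ci_high <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


class TestBuildReport:
    def test_zero_dispersion_cohort_has_zero_sems(self):
        """With dispersion 0 every animal equals its group mean, so every
        within-group SEM in the report is (numerically) 0."""
        design = CohortDesign.small(2)
        design = CohortDesign(groups=design.groups, dispersion_scale=0.0,
                              snr=1e6)
        table = simulate_cohort(design, seed=0)
        rep = build_report(table)
        sems = pd.concat([rep.comparisons["sem_a"], rep.comparisons["sem_b"]])
        assert (sems.abs() < 0.35).all()

    def test_week2_fat_contrast_power_at_study_effect_size(self, trajectory):
        """Control vs CDAHFD %fat at week 2 (19.00 vs 2.41, SEM 0.64/0.17,
        n=6): the Welch test is significant in ≥95 % of 200 replicate
        cohorts drawn at the printed moments."""
        g_cd = trajectory.lookup("cdahfd", 2)
        g_nc = trajectory.lookup("normal_chow", 2)
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(200):
            a = rng.normal(g_nc.fat_pct.mean, g_nc.fat_pct.sd(6), 6)
            b = rng.normal(g_cd.fat_pct.mean, g_cd.fat_pct.sd(6), 6)
            hits += welch_t(a, b).significant
        assert hits >= 190

    def test_fat_lv_correlation_positive_from_shared_latent(self):
        """fat_pct and lv_pct derive from one latent steatosis deviate, so
        their cohort correlation must come out positive."""
        table = simulate_cohort(CohortDesign.small(3), seed=1)
        rep = build_report(table)
        row = rep.correlations.query("x == 'fat_pct' and y == 'lv_pct'")
        assert row["r"].iloc[0] > 0

    def test_missing_columns_listed(self):
        table = pd.DataFrame({"animal_id": ["a1", "a2"], "diet": ["cdahfd"] * 2,
                              "week": [2, 2]})
        with pytest.raises(ValueError, match="t1_ms"):
            build_report(table)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            build_report(pd.DataFrame())

    def test_report_structure(self):
        table = simulate_cohort(CohortDesign.small(2), seed=2)
        rep = build_report(table)
        # every metric appears; withdrawal-vs-week-14 contrast present
        assert set(rep.comparisons["metric"]) >= {"t1_ms", "fat_pct", "cpa_pct"}
        assert (rep.comparisons["group_a"] == "withdrawal_w14").any()
        assert set(zip(rep.correlations["x"], rep.correlations["y"])) == {
            ("fat_pct", "lv_pct"), ("cpa_pct", "t1_ms"),
            ("cpa_pct", "t2star_ms"), ("cpa_pct", "auc_pct_dsnr")}
        assert "| metric |" in rep.markdown
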