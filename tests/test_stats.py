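"""Tests of the statistics battery against hand-computed formulas,
brute-force rank/permutation oracles, and generative regression slopes."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from darkadapt import (generate_cohort, kgroup_compare, normality_gate,
                       pearson_with_ci, spearman, stepwise_ols, welch_t)

# printed group summaries: (n, mean, sd), ordered control - aniridia
CONE_ANIRIDIA, CONE_CONTROL = (26, -0.84, 0.66), (37, -1.56, 0.36)
ROD_ANIRIDIA, ROD_CONTROL = (26, -3.50, 0.76), (37, -4.23, 0.34)


class TestWelch:
    def test_cone_threshold_group_difference(self):
        rep = welch_t(CONE_CONTROL, CONE_ANIRIDIA)
        assert round(rep.statistic, 1) == -5.1

    def test_rod_threshold_group_difference(self):
        rep = welch_t(ROD_CONTROL, ROD_ANIRIDIA)
        assert round(rep.statistic, 1) == -4.6
        assert rep.p_value < 1e-4

    def test_hand_formula_oracle(self):
        a = np.array([1.1, 2.3, 0.7, 1.9, 1.2])
        b = np.array([2.0, 2.8, 3.1, 2.2, 2.6])
        rep = welch_t(a, b)
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_hand = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va ** 2 / 4 + vb ** 2 / 4)
        assert rep.statistic == pytest.approx(t_hand, abs=1e-12)
        assert rep.df == pytest.approx(df_hand, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 20)
        rep = welch_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert rep.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert rep.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_raw_samples_equal_summary_triples(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 9), rng.normal(1, 1, 14)
        r1 = welch_t(a, b)
        r2 = welch_t((9, a.mean(), a.std(ddof=1)), (14, b.mean(), b.std(ddof=1)))
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)
        assert r1.df == pytest.approx(r2.df, abs=1e-12)

    def test_identical_samples_give_zero(self):
        a = np.array([1.0, 2.0, 3.0, 2.5])
        b = np.array([1.0, 2.0, 3.0, 2.5, 2.0])
        assert welch_t(a, b).statistic == pytest.approx(
            welch_t(b, a).statistic * -1)
        assert welch_t(a, a).statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            welch_t(np.ones(5), np.ones(6))


class TestPearsonCI:
    def test_printed_cone_correlation_ci(self):
        rep = pearson_with_ci(r=-0.49, n=20)
        assert round(rep.ci_low, 2) == -0.77
        assert round(rep.ci_high, 2) == -0.06
        assert rep.p_value < 0.05

    def test_printed_rod_correlation_ci(self):
        rep = pearson_with_ci(r=-0.53, n=20)
        assert round(rep.ci_low, 2) == -0.79
        assert round(rep.ci_high, 2) == -0.11

    def test_zero_correlation_gives_symmetric_ci(self):
        rep = pearson_with_ci(r=0.0, n=30)
        assert rep.ci_low == pytest.approx(-rep.ci_high, abs=1e-12)

    def test_raw_samples_match_scipy_r(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        rep = pearson_with_ci(x, y)
        assert rep.statistic == pytest.approx(sps.pearsonr(x, y).statistic,
                                              abs=1e-12)

    def test_perfect_correlation_flagged(self):
        rep = pearson_with_ci(r=1.0, n=10)
        assert rep.extra.get("degenerate") is True
        assert rep.ci_low == rep.ci_high == 1.0


class TestSpearman:
    def test_perfectly_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        assert spearman(x, x ** 3).statistic == pytest.approx(1.0)
        assert spearman(x, -np.exp(x)).statistic == pytest.approx(-1.0)

    def test_small_sample_matches_rank_formula_and_exact_p(self):
        x = np.array([1, 2, 3, 4, 5], float)
        y = np.array([2, 1, 4, 3, 5], float)
        rep = spearman(x, y)
        d = sps.rankdata(x) - sps.rankdata(y)
        rs_formula = 1 - 6 * np.sum(d ** 2) / (5 * 24)  # no ties
        assert rep.statistic == pytest.approx(rs_formula, abs=1e-12)
        # brute-force permutation p
        ry = sps.rankdata(y)
        stats = [np.corrcoef(np.array(p, float), ry)[0, 1]
                 for p in itertools.permutations(sps.rankdata(x))]
        p_brute = np.mean(np.abs(stats) >= abs(rep.statistic) - 1e-12)
        assert rep.p_value == pytest.approx(p_brute, abs=1e-12)
        assert rep.extra["method"] == "exact_permutation"

    def test_midranks_for_ties(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 2.0, 3.0, 5.0, 5.0])
        rep = spearman(x, y)
        ref = sps.spearmanr(x, y).statistic
        assert rep.statistic == pytest.approx(ref, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(6), np.arange(6.0))


class TestNormalityGate:
    def test_normal_samples_stay_parametric_most_of_the_time(self):
        rng = np.random.default_rng(2024)
        picks = []
        for _ in range(100):
            groups = {"a": rng.normal(0, 1, 40), "b": rng.normal(1, 2, 40)}
            path, _ = normality_gate(groups)
            picks.append(path == "parametric")
        # two Shapiro-Wilk tests at alpha=0.05 -> parametric ~90% of runs
        assert np.mean(picks) >= 0.85

    def test_lognormal_samples_gate_nonparametric(self):
        rng = np.random.default_rng(7)
        groups = {"a": np.exp(rng.normal(0, 1.2, 50)),
                  "b": rng.normal(0, 1, 50)}
        path, table = normality_gate(groups)
        assert path == "nonparametric"
        assert set(table["group"]) == {"a", "b"}

    def test_tiny_groups_run_without_error(self):
        path, table = normality_gate({"a": [1.0, 2.0, 3.0], "b": [1.1, 2.1, 3.4]})
        assert path in ("parametric", "nonparametric")
        assert (table["n"] == 3).all()


def brute_force_h(groups):
    """Kruskal-Wallis H from its rank-sum definition."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    h, start = 0.0, 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie


class TestKGroupCompare:
    def test_identical_groups_not_significant(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.concatenate([g, g, g])
        labels = np.repeat(["x", "y", "z"], 4)
        rep, posthoc = kgroup_compare(values, labels, path="parametric")
        assert rep.p_value > 0.99
        assert (posthoc["p_bonferroni"] >= posthoc["p_raw"] - 1e-15).all()
        assert (posthoc["p_bonferroni"] <= 1.0).all()

    def test_h_statistic_matches_brute_force_ranks(self):
        groups = [np.array([1.0, 5.0, 8.0, 2.0]),
                  np.array([3.0, 3.0, 7.0, 9.0]),
                  np.array([10.0, 11.0, 2.0, 6.0])]
        values = np.concatenate(groups)
        labels = np.repeat(["g0", "g1", "g2"], 4)
        rep, _ = kgroup_compare(values, labels, path="nonparametric")
        assert rep.test_name == "kruskal_wallis"
        assert rep.df == 2
        assert rep.statistic == pytest.approx(brute_force_h(groups), abs=1e-12)

    def test_small_level_dropped_with_warning(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 9.0, 100.0])
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"])
        rep, _ = kgroup_compare(values, labels, path="parametric")
        assert rep.extra["dropped_levels"] == ["c"]
        assert rep.n_per_group == (4, 4)

    def test_bonferroni_uses_number_of_pairs(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        _, posthoc = kgroup_compare(values, labels, path="parametric")
        assert len(posthoc) == 3
        np.testing.assert_allclose(posthoc["p_bonferroni"],
                                   np.minimum(posthoc["p_raw"] * 3, 1.0))


class TestStepwiseOLS:
    def test_recovers_generative_predictors_and_slopes(self):
        cohort = generate_cohort(2000, 2, rng_seed=31)
        ani = cohort[cohort.group == "aniridia"]
        mc = stepwise_ols("rod_threshold",
                          ["central_outer_retinal_thickness", "age", "aak_grade"],
                          ani)
        assert set(mc.selected) == {"central_outer_retinal_thickness", "age"}
        beta = mc.selected_coefficients.loc["central_outer_retinal_thickness", "beta"]
        assert beta == pytest.approx(-0.014, rel=0.2)
        beta_age = mc.selected_coefficients.loc["age", "beta"]
        assert beta_age == pytest.approx(0.019, rel=0.2)

    def test_perfect_single_predictor_r2_one(self):
        x = np.linspace(0, 10, 30)
        df = pd.DataFrame({"y": 2.0 * x - 1.0, "x": x})
        mc = stepwise_ols("y", ["x"], df)
        assert mc.selected == ("x",)
        row = mc.table[mc.table.predictors == "x"].iloc[0]
        assert row.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noise_predictor_rarely_selected(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(40):
            x = rng.normal(size=120)
            noise = rng.normal(size=120)
            y = 1.5 * x + rng.normal(size=120)
            df = pd.DataFrame({"y": y, "x": x, "noise": noise})
            mc = stepwise_ols("y", ["x", "noise"], df)
            hits += "noise" in mc.selected
        assert hits / 40 <= 0.125  # ~alpha-level inclusion of pure noise

    def test_adding_predictors_never_increases_rss(self):
        cohort = generate_cohort(100, 2, rng_seed=41)
        ani = cohort[cohort.group == "aniridia"]
        mc = stepwise_ols("cone_threshold",
                          ["central_outer_retinal_thickness", "age", "aak_grade"],
                          ani)
        tab = mc.table.set_index("predictors")
        for _, row in mc.lrt.iterrows():
            assert tab.loc[row["full"], "rss"] <= \
                tab.loc[row["reduced"] if row["reduced"] != "(intercept)" else "(intercept)",
                        "rss"] + 1e-9

    def test_rank_deficient_design_named(self):
        x = np.linspace(0, 1, 30)
        df = pd.DataFrame({"y": x + 1, "a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            stepwise_ols("y", ["a", "b"], df)

    def test_lrt_statistic_formula(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        df = pd.DataFrame({"y": y, "x": x})
        mc = stepwise_ols("y", ["x"], df)
        tab = mc.table.set_index("predictors")
        stat_hand = 50 * math.log(tab.loc["(intercept)", "rss"] / tab.loc["x", "rss"])
        row = mc.lrt.iloc[0]
        assert row["statistic"] == pytest.approx(stat_hand, abs=1e-12)
        assert row["p"] == pytest.approx(sps.chi2.sf(stat_hand, 1), abs=1e-12)
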