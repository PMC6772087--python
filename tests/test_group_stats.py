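import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bonessm.group_stats import (
    CohortTable,
    ancova_per_mode,
    anova_per_mode,
    build_cohort_table,
    ks_normality,
    run_comparison,
)


def make_table(b, groups, ages=None, genders=None, seed=0):
    rng = np.random.default_rng(seed)
    n = len(groups)
    meta = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n)],
        "instance_id": [f"S{i}_L" for i in range(n)],
        "group": groups,
        "side": ["L"] * n,
        "age": rng.uniform(18, 55, n) if ages is None else ages,
        "gender": rng.choice(["M", "F"], n) if genders is None else genders,
    })
    return build_cohort_table(meta, np.atleast_2d(np.asarray(b, float)).T
                              if np.ndim(b) == 1 else b)


@pytest.fixture
def null_table():
    rng = np.random.default_rng(0)
    groups = ["CAI"] * 26 + ["CAI_CONTRA"] * 26 + ["HEALTHY"] * 46
    return make_table(rng.standard_normal((len(groups), 3)), groups)


class TestKsNormality:
    def test_gaussian_sample_not_rejected(self):
        x = np.random.default_rng(0).standard_normal(1000)
        assert ks_normality(x) > 0.05

    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, 1000) * np.sqrt(3.0)  # unit variance
        assert ks_normality(x) < 0.05

    def test_constant_vector_degenerate(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            p = ks_normality(np.ones(10))
        assert p == 0.0

    def test_mc_and_table_methods_agree(self):
        x = np.random.default_rng(2).standard_normal(80)
        p_table = ks_normality(x, method="table")
        p_mc = ks_normality(x, method="mc", n_mc=2000, seed=0)
        assert abs(p_table - p_mc) < 0.08

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.arange(4.0))


class TestAnova:
    def test_textbook_example(self):
        """Three groups {1,2,3}, {2,3,4}, {6,7,8}: SSB=42 (df 2), SSW=6
        (df 6), so F = 21.0. Verified by hand and against scipy."""
        groups = ["CAI"] * 3 + ["CAI_CONTRA"] * 3 + ["HEALTHY"] * 3
        table = make_table([1, 2, 3, 2, 3, 4, 6, 7, 8.0], groups)
        out = anova_per_mode(table)
        omnibus = out[out["test"] == "anova"].iloc[0]
        f_scipy, p_scipy = sps.f_oneway([1, 2, 3], [2, 3, 4], [6, 7, 8])
        assert f_scipy == pytest.approx(21.0)
        assert omnibus["statistic"] == pytest.approx(21.0)
        assert omnibus["p_raw"] == pytest.approx(p_scipy, abs=1e-12)
        assert omnibus["p_raw"] == pytest.approx(0.0020, abs=2e-4)

    def test_bonferroni_is_triple_raw_capped(self, null_table):
        out = anova_per_mode(null_table)
        pairs = out[out["test"] == "bonferroni"]
        assert len(pairs) == 9  # 3 pairs x 3 modes
        assert np.allclose(pairs["p_adjusted"],
                           np.minimum(1.0, 3.0 * pairs["p_raw"]))
        assert (pairs["p_adjusted"] >= pairs["p_raw"] - 1e-15).all()

    def test_identical_groups_give_f_zero_p_one(self):
        groups = ["CAI"] * 3 + ["CAI_CONTRA"] * 3 + ["HEALTHY"] * 3
        table = make_table([1, 2, 3] * 3, groups)
        omnibus = anova_per_mode(table)
        row = omnibus[omnibus["test"] == "anova"].iloc[0]
        assert row["statistic"] == 0.0
        assert row["p_raw"] == 1.0

    def test_pooled_t_matches_explicit_formula(self, null_table):
        df = null_table.frame
        out = anova_per_mode(null_table)
        row = out[(out["test"] == "bonferroni")
                  & (out["mode"] == "b1")
                  & (out["comparison"] == "CAI vs HEALTHY")].iloc[0]
        a = df.loc[df.group == "CAI", "b1"].to_numpy()
        b = df.loc[df.group == "HEALTHY", "b1"].to_numpy()
        c = df.loc[df.group == "CAI_CONTRA", "b1"].to_numpy()
        sse = sum(np.sum((x - x.mean()) ** 2) for x in (a, b, c))
        dfw = len(df) - 3
        t = (a.mean() - b.mean()) / np.sqrt(sse / dfw * (1 / len(a) + 1 / len(b)))
        assert row["p_raw"] == pytest.approx(2 * sps.t.sf(abs(t), dfw), abs=1e-12)

    def test_small_group_flagged_unavailable(self):
        groups = ["CAI"] * 2 + ["CAI_CONTRA"] * 5 + ["HEALTHY"] * 5
        table = make_table(np.arange(12.0), groups)
        out = anova_per_mode(table)
        assert not out["available"].iloc[0]


class TestAncova:
    def test_matches_statsmodels_extra_sum_of_squares(self, null_table):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        out = ancova_per_mode(null_table)
        df = null_table.frame
        full = smf.ols("b1 ~ C(group) + age + C(gender)", data=df).fit()
        red = smf.ols("b1 ~ age + C(gender)", data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = anova_lm(red, full)
        p_sm = float(table["Pr(>F)"].iloc[1])
        assert out.iloc[0]["p_raw"] == pytest.approx(p_sm, abs=1e-10)

    def test_single_gender_dropped_with_warning(self):
        groups = ["CAI"] * 8 + ["CAI_CONTRA"] * 8 + ["HEALTHY"] * 8
        table = make_table(np.random.default_rng(3).normal(size=24), groups,
                           genders=["F"] * 24)
        with pytest.warns(RuntimeWarning, match="gender"):
            out = ancova_per_mode(table)
        assert np.isfinite(out.iloc[0]["p_raw"])

    def test_zero_covariate_effect_tracks_anova(self):
        # with no covariate effect the adjustment is unbiased: the signed
        # p difference averages out, its magnitude stays at the level set by
        # the two lost residual df (~0.04 by simulation at n=60)
        rng = np.random.default_rng(4)
        groups = ["CAI"] * 20 + ["CAI_CONTRA"] * 20 + ["HEALTHY"] * 20
        diffs = []
        for _ in range(60):
            table = make_table(rng.standard_normal(60), groups,
                               seed=int(rng.integers(1000)))
            pa = anova_per_mode(table)
            pa = pa[pa["test"] == "anova"].iloc[0]["p_raw"]
            pc = ancova_per_mode(table).iloc[0]["p_raw"]
            diffs.append(pa - pc)
        assert abs(np.mean(diffs)) < 0.02
        assert np.mean(np.abs(diffs)) < 0.08

    def test_age_confound_weakens_group_effect(self):
        # the group difference is entirely mediated by a planted age effect;
        # adjusting for age must (usually) raise the group p-value
        rng = np.random.default_rng(5)
        wins = 0
        reps = 100
        for _ in range(reps):
            n = 20
            groups = ["CAI"] * n + ["CAI_CONTRA"] * n + ["HEALTHY"] * n
            age = np.concatenate([rng.uniform(35, 55, 2 * n),
                                  rng.uniform(18, 38, n)])
            b = 0.05 * (age - age.mean()) + rng.standard_normal(3 * n) * 0.3
            table = make_table(b, groups, ages=age)
            pa = anova_per_mode(table)
            pa = pa[pa["test"] == "anova"].iloc[0]["p_raw"]
            pc = ancova_per_mode(table).iloc[0]["p_raw"]
            wins += pc > pa
        assert wins / reps >= 0.90

    def test_missing_covariates_rejected(self, null_table):
        null_table.frame.loc[0, "age"] = np.nan
        with pytest.raises(ValueError, match="age and gender"):
            ancova_per_mode(null_table)


class TestRunComparison:
    def test_alpha_one_flags_every_comparison(self, null_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_comparison(null_table, alpha=1.0)
        assert all(res.flags.values())
        assert len(res.flags) == 3 * null_table.n_modes

    def test_pvalues_within_unit_interval(self, null_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_comparison(null_table)
        p = res.table[["p_raw", "p_adjusted"]].to_numpy(float)
        p = p[np.isfinite(p)]
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_planted_difference_flagged_on_right_pairs(self):
        rng = np.random.default_rng(6)
        groups = ["CAI"] * 26 + ["CAI_CONTRA"] * 26 + ["HEALTHY"] * 46
        b = rng.standard_normal((len(groups), 2))
        b[np.asarray(groups) != "HEALTHY", 1] += 1.0  # effect on mode 2 only
        table = make_table(b, groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_comparison(table)
        sig = res.significant_modes()
        assert ("CAI", "HEALTHY") in sig["b2"]
        assert ("CAI_CONTRA", "HEALTHY") in sig["b2"]
        assert ("CAI", "CAI_CONTRA") not in sig.get("b2", [])

    def test_non_independence_warning_emitted(self, null_table):
        with pytest.warns(UserWarning, match="share subjects"):
            run_comparison(null_table)

    def test_one_per_subject_policy_drops_duplicate_ankles(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(10):  # bilateral healthy controls
            for side in ("L", "R"):
                rows.append({"subject_id": f"H{i}", "instance_id": f"H{i}_{side}",
                             "group": "HEALTHY", "side": side,
                             "age": 30.0, "gender": "F"})
        for i in range(10):
            for grp, side in (("CAI", "L"), ("CAI_CONTRA", "R")):
                rows.append({"subject_id": f"P{i}", "instance_id": f"P{i}_{side}",
                             "group": grp, "side": side,
                             "age": 30.0, "gender": "M"})
        meta = pd.DataFrame(rows)
        table = build_cohort_table(meta, rng.standard_normal((len(meta), 1)))
        restricted = table.restrict_healthy("one-per-subject", seed=0)
        healthy = restricted.frame[restricted.frame.group == "HEALTHY"]
        assert healthy["subject_id"].value_counts().max() == 1
        assert (restricted.frame.group != "HEALTHY").sum() == 20


class TestCohortTableValidation:
    def test_duplicate_side_rejected(self):
        meta = pd.DataFrame({
            "subject_id": ["A", "A"], "instance_id": ["A_L", "A_L2"],
            "group": ["CAI", "CAI"], "side": ["L", "L"],
            "age": [30, 30], "gender": ["M", "M"],
        })
        with pytest.raises(ValueError, match="per side"):
            build_cohort_table(meta, np.zeros((2, 1)))

    def test_unknown_group_rejected(self):
        meta = pd.DataFrame({
            "subject_id": ["A"], "instance_id": ["A_L"], "group": ["SPRAINED"],
            "side": ["L"], "age": [30], "gender": ["M"],
        })
        with pytest.raises(ValueError, match="unknown group"):
            build_cohort_table(meta, np.zeros((1, 1)))

    def test_missing_b_rejected(self):
        meta = pd.DataFrame({
            "subject_id": ["A", "B", "C"], "instance_id": ["A_L", "B_L", "C_L"],
            "group": ["CAI", "CAI", "HEALTHY"], "side": ["L"] * 3,
            "age": [30] * 3, "gender": ["M"] * 3,
        })
        b = np.zeros((3, 2))
        b[1, 1] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            build_cohort_table(meta, b)
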