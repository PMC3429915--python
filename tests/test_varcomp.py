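"""ANOVA and variance-component tests against brute-force and statsmodels oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from riqtl import (
    adjusted_n,
    anova_three_way,
    compute_fattiness,
    genetic_correlation,
    heritability_by_cohort,
    percent_fat,
    strain_means,
    variance_components,
)
from riqtl.traits import TraitVector
from riqtl.varcomp import TERMS, type3_anova


def trait_from(df: pd.DataFrame) -> TraitVector:
    vals = pd.Series(df["y"].to_numpy(), index=df["animal_id"], name="y")
    return TraitVector(vals, "y", "raw")


def toy_balanced(values=None, reps=2, n_strain=2, seed=0):
    """Balanced 2 x 2 x n_strain x reps table with integer-ish values."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for s in [f"S{k}" for k in range(n_strain)]:
        for x in ("F", "M"):
            for d in ("HF", "LF"):
                for _ in range(reps):
                    y = float(rng.integers(0, 10)) if values is None else values[i]
                    rows.append(
                        {
                            "animal_id": f"a{i}",
                            "strain": s,
                            "sex": x,
                            "diet": d,
                            "fat_mg": 1.0,
                            "lean_mg": 1.0,
                            "y": y,
                        }
                    )
                    i += 1
    return pd.DataFrame(rows)


def brute_force_balanced_ss(df: pd.DataFrame) -> dict[str, float]:
    """Direct mean-deviation SS decomposition, valid for balanced designs."""
    y = df["y"].to_numpy(float)
    grand = y.mean()
    n = len(y)

    def level_means(cols):
        return df.groupby(cols)["y"].mean()

    def ss_main(col):
        m = level_means([col])
        counts = df.groupby([col])["y"].size()
        return float((counts * (m - grand) ** 2).sum())

    ss = {c: ss_main(c) for c in ("sex", "diet", "strain")}

    def ss_two(c1, c2):
        m12 = level_means([c1, c2])
        m1 = level_means([c1])
        m2 = level_means([c2])
        counts = df.groupby([c1, c2])["y"].size()
        total = 0.0
        for (l1, l2), mean12 in m12.items():
            dev = mean12 - m1[l1] - m2[l2] + grand
            total += counts[(l1, l2)] * dev**2
        return float(total)

    ss["sex:diet"] = ss_two("sex", "diet")
    ss["sex:strain"] = ss_two("sex", "strain")
    ss["diet:strain"] = ss_two("diet", "strain")

    m123 = level_means(["sex", "diet", "strain"])
    m12 = level_means(["sex", "diet"])
    m13 = level_means(["sex", "strain"])
    m23 = level_means(["diet", "strain"])
    m1 = level_means(["sex"])
    m2 = level_means(["diet"])
    m3 = level_means(["strain"])
    counts = df.groupby(["sex", "diet", "strain"])["y"].size()
    total = 0.0
    for (l1, l2, l3), mean in m123.items():
        dev = (
            mean
            - m12[(l1, l2)]
            - m13[(l1, l3)]
            - m23[(l2, l3)]
            + m1[l1]
            + m2[l2]
            + m3[l3]
            - grand
        )
        total += counts[(l1, l2, l3)] * dev**2
    ss["sex:diet:strain"] = float(total)
    ss["residual"] = float(
        sum(
            ((df.loc[g.index, "y"] - g.mean()) ** 2).sum()
            for _, g in df.groupby(["sex", "diet", "strain"])["y"]
        )
    )
    return ss


class TestAnova:
    def test_balanced_ss_match_brute_force(self):
        df = toy_balanced(seed=4)
        table = anova_three_way(trait_from(df), df)
        oracle = brute_force_balanced_ss(df)
        for term in (*TERMS, "residual"):
            assert table.loc[term, "ss"] == pytest.approx(
                oracle[term], rel=1e-8, abs=1e-10
            ), term

    def test_balanced_ss_sum_to_total(self):
        df = toy_balanced(reps=3, n_strain=4, seed=5)
        table = anova_three_way(trait_from(df), df)
        total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert table["ss"].sum() == pytest.approx(total, rel=1e-10)

    def test_unbalanced_type3_matches_statsmodels(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(6)
        df = toy_balanced(reps=4, n_strain=3, seed=6)
        df = df.drop(df.sample(n=10, random_state=1).index).reset_index(drop=True)
        table = anova_three_way(trait_from(df), df)

        fit = smf.ols("y ~ C(sex, Sum)*C(diet, Sum)*C(strain, Sum)", df).fit()
        sm_tbl = anova_lm(fit, typ=3)
        pairs = {
            "sex": "C(sex, Sum)",
            "diet": "C(diet, Sum)",
            "strain": "C(strain, Sum)",
            "sex:diet": "C(sex, Sum):C(diet, Sum)",
            "sex:strain": "C(sex, Sum):C(strain, Sum)",
            "diet:strain": "C(diet, Sum):C(strain, Sum)",
            "sex:diet:strain": "C(sex, Sum):C(diet, Sum):C(strain, Sum)",
            "residual": "Residual",
        }
        for mine, theirs in pairs.items():
            assert table.loc[mine, "ss"] == pytest.approx(
                float(sm_tbl.loc[theirs, "sum_sq"]), rel=1e-8
            ), mine

    def test_mixed_model_denominators(self):
        df = toy_balanced(reps=3, n_strain=4, seed=7)
        table = anova_three_way(trait_from(df), df)
        assert table.loc["sex", "denom"] == "sex:strain"
        assert table.loc["diet", "denom"] == "diet:strain"
        assert table.loc["sex:diet", "denom"] == "sex:diet:strain"
        assert table.loc["strain", "denom"] == "residual"
        # F recomputed from the table's own mean squares
        f = table.loc["sex", "ms"] / table.loc["sex:strain", "ms"]
        assert table.loc["sex", "F"] == pytest.approx(f)

    def test_constant_trait_zero_ss_missing_f(self):
        df = toy_balanced(values=[5.0] * 16)
        table = anova_three_way(trait_from(df), df)
        assert table["ss"].to_numpy() == pytest.approx([0.0] * 8, abs=1e-18)
        assert table["F"].drop("residual").isna().all()

    def test_missing_factor_level_rejected(self):
        df = toy_balanced()
        with pytest.raises(ValueError):
            anova_three_way(trait_from(df[df.sex == "F"]), df[df.sex == "F"])

    def test_strain_type1_error_calibrated_under_null(self):
        """No genetic variance: strain-term p below 0.05 ~5% of the time."""
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            df = toy_balanced(reps=3, n_strain=6, seed=rng.integers(2**31))
            df["y"] = rng.normal(size=len(df))
            table = anova_three_way(trait_from(df), df)
            hits += table.loc["strain", "p"] < 0.05
        # 3 sigma binomial band around 0.05
        assert abs(hits / n_rep - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_rep)


class TestAdjustedN:
    def test_formula_values(self):
        assert adjusted_n([2, 4, 6]) == pytest.approx((12 - 56 / 12) / 2)
        assert adjusted_n([8] * 5) == pytest.approx(8.0)
        assert adjusted_n([1, 1]) == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            adjusted_n([7])


class TestVarianceComponents:
    def test_no_between_strain_signal_gives_zero_h2(self):
        df = toy_balanced(reps=4, n_strain=4, seed=9)
        # per-animal iid noise -> MS_str ~ MS_r; engineer exact equality
        table = anova_three_way(trait_from(df), df)
        table.loc["strain", "ms"] = table.loc["residual", "ms"]
        res = variance_components(table, df)
        assert res.raw["strain"] == pytest.approx(0.0, abs=1e-12)
        assert res.H2 == pytest.approx(0.0, abs=1e-12)

    def test_negative_component_truncated(self):
        df = toy_balanced(reps=4, n_strain=4, seed=10)
        table = anova_three_way(trait_from(df), df)
        table.loc["strain", "ms"] = 0.5 * table.loc["residual", "ms"]
        res = variance_components(table, df)
        assert res.raw["strain"] < 0
        assert res.truncated["strain"] == 0.0
        assert 0 <= res.H2 <= 1

    def test_h2_affine_invariance(self):
        df = toy_balanced(reps=5, n_strain=6, seed=11)
        rng = np.random.default_rng(11)
        strain_eff = {f"S{k}": rng.normal(0, 1) for k in range(6)}
        df["y"] = df["strain"].map(strain_eff) + rng.normal(0, 2, len(df))
        t1 = anova_three_way(trait_from(df), df)
        h2_a = variance_components(t1, df).H2
        df2 = df.copy()
        df2["y"] = 3.0 * df2["y"] - 7.0
        t2 = anova_three_way(trait_from(df2), df2)
        h2_b = variance_components(t2, df2).H2
        assert h2_a == pytest.approx(h2_b, rel=1e-10)
        assert 0 <= h2_a <= 1

    def test_components_use_their_own_grouping_n(self):
        df = toy_balanced(reps=4, n_strain=4, seed=12)
        table = anova_three_way(trait_from(df), df)
        res = variance_components(table, df)
        # balanced: n0 per grouping = animals per cell of that grouping
        assert res.adjusted_n["strain"] == pytest.approx(16.0)
        assert res.adjusted_n["sex:strain"] == pytest.approx(8.0)
        assert res.adjusted_n["sex:diet:strain"] == pytest.approx(4.0)


class TestCohortHeritability:
    def make(self, per_strain_values):
        rows = []
        i = 0
        for s, vals in per_strain_values.items():
            for v in vals:
                rows.append(
                    {
                        "animal_id": f"a{i}",
                        "strain": s,
                        "sex": "F",
                        "diet": "HF",
                        "fat_mg": 1.0,
                        "lean_mg": 1.0,
                        "y": v,
                    }
                )
                i += 1
        df = pd.DataFrame(rows)
        return trait_from(df), df

    def test_all_between_strain_variance_gives_one(self):
        trait, df = self.make({"A": [1.0, 1.0], "B": [3.0, 3.0]})
        assert heritability_by_cohort(trait, df, "F", "HF") == pytest.approx(1.0)

    def test_equal_strain_means_give_zero(self):
        trait, df = self.make({"A": [1.0, 3.0], "B": [3.0, 1.0]})
        assert heritability_by_cohort(trait, df, "F", "HF") == pytest.approx(0.0)

    def test_too_few_strains_rejected(self):
        trait, df = self.make({"A": [1.0, 2.0]})
        with pytest.raises(ValueError):
            heritability_by_cohort(trait, df, "F", "HF")

    def test_designed_ratio_recovered(self):
        """sigma2_str / (sigma2_str + sigma2_r) = 0.5: mean estimate close."""
        rng = np.random.default_rng(13)
        h2s = []
        for _ in range(150):
            per_strain = {
                f"S{k}": rng.normal(rng.normal(0, 1.0), 1.0, size=12)
                for k in range(12)
            }
            trait, df = self.make(per_strain)
            h2s.append(heritability_by_cohort(trait, df, "F", "HF"))
        assert np.mean(h2s) == pytest.approx(0.5, abs=0.06)


class TestGeneticCorrelation:
    def test_affine_relation_gives_unit_correlation(self):
        a = pd.Series([1.0, 2, 3, 5, 8], index=list("ABCDE"))
        r, r2 = genetic_correlation(a, 2 * a + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_hand_pearson_five_points(self):
        a = pd.Series([1.0, 2, 3, 4, 5], index=list("ABCDE"))
        b = pd.Series([2.0, 1, 4, 3, 6], index=list("ABCDE"))
        av, bv = a.to_numpy(), b.to_numpy()
        cov = ((av - av.mean()) * (bv - bv.mean())).sum() / 4
        oracle = cov / (av.std(ddof=1) * bv.std(ddof=1))
        r, r2 = genetic_correlation(a, b)
        assert r == pytest.approx(oracle, rel=1e-12)
        assert r2 == pytest.approx(oracle**2, rel=1e-12)

    def test_constant_vector_flagged(self):
        a = pd.Series([1.0, 1, 1], index=list("ABC"))
        b = pd.Series([1.0, 2, 3], index=list("ABC"))
        r, r2 = genetic_correlation(a, b)
        assert math.isnan(r) and math.isnan(r2)

    def test_too_few_common_strains_rejected(self):
        a = pd.Series([1.0, 2], index=list("AB"))
        with pytest.raises(ValueError):
            genetic_correlation(a, a)

    def test_shared_vs_independent_strain_effects(self):
        """Same strain effects in both diets -> r near 1; independent -> r near 0."""
        rng = np.random.default_rng(14)
        rs_shared, rs_indep = [], []
        for _ in range(60):
            eff = rng.normal(0, 1, 20)
            idx = [f"S{i}" for i in range(20)]
            shared_hf = pd.Series(eff + rng.normal(0, 0.1, 20), index=idx)
            shared_lf = pd.Series(eff + rng.normal(0, 0.1, 20), index=idx)
            rs_shared.append(genetic_correlation(shared_hf, shared_lf)[0])
            indep_hf = pd.Series(rng.normal(0, 1, 20), index=idx)
            indep_lf = pd.Series(rng.normal(0, 1, 20), index=idx)
            rs_indep.append(genetic_correlation(indep_hf, indep_lf)[0])
        assert np.median(rs_shared) > 0.95
        assert abs(np.mean(rs_indep)) < 0.1


def test_strain_means_groupings(small_panel):
    _, _, pheno, _ = small_panel
    trait = compute_fattiness(pheno)
    overall = strain_means(trait, pheno)
    assert len(overall) == pheno["strain"].nunique()
    by_diet = strain_means(trait, pheno, by=("diet",))
    assert set(by_diet.columns) == {"HF", "LF"}
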