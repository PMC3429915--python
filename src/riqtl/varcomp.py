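"""Mixed-model ANOVA, variance components and broad-sense heritability.

The quantitative-genetic workhorse for an RI panel: a three-way factorial
ANOVA of the trait with fixed sex and diet and random strain,

    Y_ijk = mu + Sex_i + Diet_j + Strain_k + Sex x Diet + Sex x Strain
          + Diet x Strain + Sex x Diet x Strain + e_ijk.

Because all animals within a strain are genetically identical, the
between-strain variance is the total genetic variance.  Variance
components come from the method-of-moments mean-square contrasts

    sigma2_str     = (MS_str     - MS_r) / n0
    sigma2_sexstr  = (MS_sexstr  - MS_r) / n0
    sigma2_dietstr = (MS_dietstr - MS_r) / n0
    sigma2_sds     = (MS_sds     - MS_r) / n0

where n0 is the unequal-group-size adjusted n of Sokal & Rohlf,
n0 = (N - sum(n_i^2)/N) / (a - 1), computed with each component's own
grouping (strain cells, sex-by-strain cells, ...).  Broad-sense
heritability is H2 = sigma2_str / (sigma2_str + sigma2_r), and the
interaction heritabilities (dietary response, sexual dimorphism,
three-way) use the same ratio with the interaction component in the
numerator.

Sums of squares are Type III from the sum-to-zero coded full factorial
fit (the design is unbalanced whenever breeding success varies between
strains).  F denominators follow the classical mixed-model expected mean
squares: each fixed effect is tested against its interaction with the
random strain factor, and strain plus all strain interactions against
the residual.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simgen import DIETS, SEXES
from .traits import TraitVector, attach_trait

logger = logging.getLogger("riqtl")

_LSTSQ_RCOND = None  # numpy default

TERMS = (
    "sex",
    "diet",
    "strain",
    "sex:diet",
    "sex:strain",
    "diet:strain",
    "sex:diet:strain",
)

# mixed-model F denominators (expected mean squares)
DENOMS = {
    "sex": "sex:strain",
    "diet": "diet:strain",
    "sex:diet": "sex:diet:strain",
    "strain": "residual",
    "sex:strain": "residual",
    "diet:strain": "residual",
    "sex:diet:strain": "residual",
}


# ---------------------------------------------------------------------------
# Sum-to-zero design construction
# ---------------------------------------------------------------------------

def _sum_code(values: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    k = len(levels)
    out = np.zeros((len(values), k - 1))
    last = levels[-1]
    for j, lev in enumerate(levels[:-1]):
        out[values == lev, j] = 1.0
    out[values == last, :] = -1.0
    return out


def _interaction(*blocks: np.ndarray) -> np.ndarray:
    """Column-wise tensor product of coded factor blocks."""
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(len(out), -1)
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=_LSTSQ_RCOND)
    r = y - X @ beta
    return float(r @ r)


def type3_anova(
    y: np.ndarray, factors: dict[str, np.ndarray], terms: tuple[str, ...]
) -> pd.DataFrame:
    """Type-III sums of squares for a factorial OLS model.

    ``factors`` maps factor name -> per-observation level array; ``terms``
    lists the model terms as ':'-joined factor names.  Each term's SS is
    the increase in residual SS when its columns are dropped from the
    otherwise full sum-to-zero coded design, the standard marginal
    (SAS Type III) decomposition.
    """
    n = len(y)
    coded: dict[str, np.ndarray] = {}
    levels: dict[str, list] = {}
    for name, vals in factors.items():
        vals = np.asarray(vals)
        levels[name] = sorted(pd.unique(vals).tolist())
        if len(levels[name]) < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
        coded[name] = _sum_code(vals, levels[name])

    blocks: dict[str, np.ndarray] = {}
    for term in terms:
        parts = term.split(":")
        blocks[term] = _interaction(*(coded[p] for p in parts))

    X_full = np.column_stack([np.ones(n)] + [blocks[t] for t in terms])
    p_full = X_full.shape[1]
    rank = np.linalg.matrix_rank(X_full)
    if rank < p_full:
        raise ValueError(
            f"singular design: rank {rank} < {p_full} columns "
            "(empty factorial cells make Type-III SS inestimable)"
        )
    rss_full = _rss(X_full, y)
    df_resid = n - p_full

    rows = []
    for term in terms:
        X_red = np.column_stack(
            [np.ones(n)] + [blocks[t] for t in terms if t != term]
        )
        ss = max(_rss(X_red, y) - rss_full, 0.0)
        df = blocks[term].shape[1]
        rows.append({"term": term, "ss": ss, "df": df, "ms": ss / df})
    rows.append(
        {
            "term": "residual",
            "ss": rss_full,
            "df": df_resid,
            "ms": rss_full / df_resid if df_resid > 0 else math.nan,
        }
    )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def anova_three_way(trait: TraitVector, pheno: pd.DataFrame) -> pd.DataFrame:
    """Three-way mixed ANOVA table for sex x diet x strain.

    Returns one row per term plus the residual, with Type-III SS, df, MS,
    and F/p computed against the mixed-model denominator recorded in the
    ``denom`` column.  A constant trait yields all-zero SS with F and p
    reported missing.
    """
    df = attach_trait(pheno, trait)
    for col, lv in (("sex", SEXES), ("diet", DIETS)):
        present = set(df[col])
        if len(present) < 2:
            raise ValueError(f"need both {col} levels, found {sorted(present)}")
    if df["strain"].nunique() < 2:
        raise ValueError("need >= 2 strains")

    y = df["y"].to_numpy(float)
    if np.ptp(y) == 0:
        # constant trait: every SS is exactly zero and no F test exists
        table = type3_anova(
            np.zeros_like(y),
            {
                "sex": df["sex"].to_numpy(),
                "diet": df["diet"].to_numpy(),
                "strain": df["strain"].to_numpy(),
            },
            TERMS,
        )
        table[["ss", "ms"]] = 0.0
        table["F"] = math.nan
        table["p"] = math.nan
        table["denom"] = [DENOMS.get(t, "") for t in table.index]
        return table
    table = type3_anova(
        y,
        {
            "sex": df["sex"].to_numpy(),
            "diet": df["diet"].to_numpy(),
            "strain": df["strain"].to_numpy(),
        },
        TERMS,
    )

    fvals, pvals, denoms = [], [], []
    for term in table.index:
        if term == "residual":
            fvals.append(math.nan)
            pvals.append(math.nan)
            denoms.append("")
            continue
        denom = DENOMS[term]
        ms_d = table.loc[denom, "ms"]
        ms_n = table.loc[term, "ms"]
        if not np.isfinite(ms_d) or ms_d <= 0 or not np.isfinite(ms_n):
            f = p = math.nan
        else:
            f = ms_n / ms_d
            p = float(stats.f.sf(f, table.loc[term, "df"], table.loc[denom, "df"]))
        fvals.append(f)
        pvals.append(p)
        denoms.append(denom)
    table["F"] = fvals
    table["p"] = pvals
    table["denom"] = denoms
    return table


def adjusted_n(counts) -> float:
    """Sokal-Rohlf adjusted group size for unequal samples.

    n0 = (N - sum(n_i^2) / N) / (a - 1) for a groups totalling N animals;
    collapses to the common n when groups are balanced.
    """
    counts = np.asarray(list(counts), float)
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    if np.any(counts < 1):
        raise ValueError("all group counts must be >= 1")
    N = counts.sum()
    return float((N - (counts**2).sum() / N) / (len(counts) - 1))


@dataclass
class VarianceComponentsResult:
    """Method-of-moments variance components and heritabilities."""

    adjusted_n: dict[str, float]
    raw: dict[str, float]          # may be negative
    truncated: dict[str, float]    # clipped at zero
    sigma2_residual: float
    H2: float
    H2_dietary_response: float
    H2_sexual_dimorphism: float
    H2_threeway: float
    H2_by_cohort: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "adjusted_n": self.adjusted_n,
            "sigma2_raw": self.raw,
            "sigma2": self.truncated,
            "sigma2_residual": self.sigma2_residual,
            "H2": self.H2,
            "H2_dietary_response": self.H2_dietary_response,
            "H2_sexual_dimorphism": self.H2_sexual_dimorphism,
            "H2_threeway": self.H2_threeway,
            "H2_by_cohort": self.H2_by_cohort,
        }


_COMPONENT_GROUPING = {
    "strain": ("strain",),
    "sex:strain": ("sex", "strain"),
    "diet:strain": ("diet", "strain"),
    "sex:diet:strain": ("sex", "diet", "strain"),
}


def _h2(sigma2: float, sigma2_r: float) -> float:
    s = max(float(sigma2), 0.0)
    sigma2_r = float(sigma2_r)
    return s / (s + sigma2_r) if (s + sigma2_r) > 0 else math.nan


def variance_components(
    anova: pd.DataFrame, pheno: pd.DataFrame
) -> VarianceComponentsResult:
    """Variance components from ANOVA mean squares with adjusted n.

    Each strain-containing component uses the mean-square contrast against
    the residual divided by the Sokal-Rohlf n0 of its own grouping
    (strain cells for the strain component, sex-by-strain cells for the
    sexual-dimorphism component, ...).  Raw components may be negative by
    sampling error; they are truncated at zero only where a bounded
    heritability requires it, and both values are reported.
    """
    ms_r = float(anova.loc["residual", "ms"])
    n0: dict[str, float] = {}
    raw: dict[str, float] = {}
    trunc: dict[str, float] = {}
    for term, grouping in _COMPONENT_GROUPING.items():
        counts = pheno.groupby(list(grouping), sort=False).size()
        n0[term] = adjusted_n(counts)
        comp = (float(anova.loc[term, "ms"]) - ms_r) / n0[term]
        raw[term] = comp
        trunc[term] = max(comp, 0.0)
        if comp < 0:
            logger.warning(
                "negative %s variance component %.4g truncated to 0", term, comp
            )
    return VarianceComponentsResult(
        adjusted_n=n0,
        raw=raw,
        truncated=trunc,
        sigma2_residual=ms_r,
        H2=_h2(raw["strain"], ms_r),
        H2_dietary_response=_h2(raw["diet:strain"], ms_r),
        H2_sexual_dimorphism=_h2(raw["sex:strain"], ms_r),
        H2_threeway=_h2(raw["sex:diet:strain"], ms_r),
    )


def heritability_by_cohort(
    trait: TraitVector, pheno: pd.DataFrame, sex: str, diet: str
) -> float:
    """Broad-sense heritability within one sex-diet cohort.

    One-way random-effects ANOVA of the trait on strain restricted to the
    cohort, with the cohort-specific adjusted n.
    """
    df = attach_trait(pheno, trait)
    sub = df[(df["sex"] == sex) & (df["diet"] == diet)]
    counts = sub.groupby("strain", sort=False).size()
    counts = counts[counts >= 2]
    if len(counts) < 2:
        raise ValueError(f"cohort {sex}/{diet}: need >= 2 strains with >= 2 animals")
    sub = sub[sub["strain"].isin(counts.index)]
    y = sub["y"].to_numpy(float)
    groups = sub["strain"].to_numpy()

    grand = y.mean()
    ss_between = sum(
        len(y[groups == g]) * (y[groups == g].mean() - grand) ** 2
        for g in counts.index
    )
    ss_within = sum(
        ((y[groups == g] - y[groups == g].mean()) ** 2).sum() for g in counts.index
    )
    df_b = len(counts) - 1
    df_w = len(y) - len(counts)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w if df_w > 0 else math.nan
    sigma2_str = (ms_b - ms_w) / adjusted_n(counts)
    return _h2(sigma2_str, ms_w)


def strain_means(
    trait: TraitVector, pheno: pd.DataFrame, by: tuple[str, ...] = ()
) -> pd.Series | pd.DataFrame:
    """Strain-level trait means, optionally stratified by sex and/or diet.

    With ``by=()`` returns one mean per strain pooled over sexes and diets
    (the input for between-trait genetic correlations); with e.g.
    ``by=("diet",)`` returns a strain x diet table used for the
    between-environment correlation of a single trait.
    """
    df = attach_trait(pheno, trait)
    if not by:
        return df.groupby("strain", sort=True)["y"].mean()
    wide = df.groupby(["strain", *by], sort=True)["y"].mean().unstack(list(by))
    return wide


def genetic_correlation(means_a: pd.Series, means_b: pd.Series) -> tuple[float, float]:
    """Between-strain Pearson correlation of two strain-mean vectors.

    RI strain means average out within-strain environmental noise, so
    their correlation estimates the correlation of genetic effects;
    r^2 is the conventional "shared genetic variance".  Returns (r, r2);
    r is NaN (flagged) when either vector is constant.
    """
    common = means_a.index.intersection(means_b.index)
    if len(common) < 3:
        raise ValueError("need >= 3 strains common to both trait vectors")
    a = means_a.loc[common].to_numpy(float)
    b = means_b.loc[common].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("zero variance in a strain-mean vector; correlation undefined")
        return math.nan, math.nan
    r = float(stats.pearsonr(a, b).statistic)
    return r, r * r
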