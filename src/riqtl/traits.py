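"""Trait derivation: fattiness residuals, percent fat, cohort means, dietary response.

The primary analysis trait is "liver fattiness": the residual of liver fat
mass regressed on liver lean mass over the whole sample, which removes the
dependence of fat mass on liver size.  Percent liver fat, fat/(fat+lean),
is the descriptive companion trait used for strain-level dietary-response
summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simgen import DIETS, validate_phenotypes

logger = logging.getLogger("riqtl")


@dataclass(frozen=True)
class TraitVector:
    """Per-animal trait values with a derivation tag."""

    values: pd.Series  # indexed by animal_id
    trait_name: str
    derivation: str  # fattiness_residual | percent_fat | raw


def compute_fattiness(
    pheno: pd.DataFrame, per_cohort: bool = False
) -> TraitVector:
    """Residuals of fat mass regressed on lean mass ("liver fattiness").

    The regression is ordinary least squares pooled over every animal in
    the table (one slope for all sexes, diets and strains), so residuals
    sum to zero over the full sample.  ``per_cohort=True`` instead fits a
    separate regression within each sex-diet cohort.
    """
    validate_phenotypes(pheno)
    if len(pheno) < 3:
        raise ValueError("need at least 3 animals for the fat-on-lean regression")

    def _resid(df: pd.DataFrame) -> pd.Series:
        lean = df["lean_mg"].to_numpy(float)
        fat = df["fat_mg"].to_numpy(float)
        if np.ptp(lean) == 0:
            raise ValueError("lean masses all equal; regression slope undefined")
        slope, intercept = np.polyfit(lean, fat, 1)
        return pd.Series(fat - (slope * lean + intercept), index=df["animal_id"])

    if per_cohort:
        parts = [
            _resid(sub) for _, sub in pheno.groupby(["sex", "diet"], sort=False)
        ]
        values = pd.concat(parts).reindex(pheno["animal_id"])
    else:
        values = _resid(pheno)
    return TraitVector(values.rename("fattiness"), "fattiness", "fattiness_residual")


def percent_fat(pheno: pd.DataFrame) -> TraitVector:
    """Fat fraction fat/(fat+lean) per animal, in [0, 1].

    Records with zero total mass carry no information about composition
    and are dropped with a warning.
    """
    validate_phenotypes(pheno)
    fat = pheno["fat_mg"].to_numpy(float)
    lean = pheno["lean_mg"].to_numpy(float)
    total = fat + lean
    keep = total > 0
    if not keep.all():
        logger.warning("dropping %d animals with zero total mass", (~keep).sum())
    values = pd.Series(
        fat[keep] / total[keep], index=pheno.loc[keep, "animal_id"], name="percent_fat"
    )
    return TraitVector(values, "percent_fat", "percent_fat")


def attach_trait(pheno: pd.DataFrame, trait: TraitVector) -> pd.DataFrame:
    """Phenotype table restricted to animals with a trait value, plus a 'y' column."""
    merged = (
        pheno.drop(columns=["y"], errors="ignore")
        .set_index("animal_id")
        .join(trait.values.rename("y"), how="inner")
    )
    return merged.reset_index()


def cohort_means(trait: TraitVector, pheno: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD (n-1 denominator) and n of the trait per strain-sex-diet cohort.

    These cohort means are the unit of observation for the strain-mean QTL
    scan: a full panel of 18 strains x 2 sexes x 2 diets yields 72 rows.
    Cells with a single animal keep their mean but report SD as missing.
    """
    df = attach_trait(pheno, trait)
    rows = []
    for (strain, sex, diet), sub in df.groupby(["strain", "sex", "diet"], sort=True):
        y = sub["y"].to_numpy(float)
        rows.append(
            {
                "strain": strain,
                "sex": sex,
                "diet": diet,
                "mean": float(y.mean()),
                "sd": float(y.std(ddof=1)) if len(y) > 1 else math.nan,
                "n": int(len(y)),
            }
        )
    out = pd.DataFrame(rows)
    logger.info("cohort means: %d cells from %d animals", len(out), len(df))
    return out


def pooled_mean(means: pd.DataFrame) -> float:
    """n-weighted grand mean over cohort cells (reconstructs the overall mean)."""
    return float(np.average(means["mean"], weights=means["n"]))


def dietary_response(
    means: pd.DataFrame, trait: TraitVector | None = None, pheno: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per strain and sex: percent change of the trait on the high-fat diet.

    percent_increase = 100 * (HF mean - LF mean) / LF mean.  When individual
    data are supplied the HF/LF contrast is additionally tested with a
    two-sided Welch two-sample t-test (robust to unequal cohort variances
    and sizes); pairs where either diet cell has n < 2 get the percent
    change where computable but a missing p-value, mirroring designs where
    a cohort holds a single animal.
    """
    have_data = trait is not None and pheno is not None
    df = attach_trait(pheno, trait) if have_data else None
    rows = []
    for (strain, sex), sub in means.groupby(["strain", "sex"], sort=True):
        cells = {d: sub.loc[sub["diet"] == d] for d in DIETS}
        if any(c.empty for c in cells.values()):
            continue
        hf_mean = float(cells["HF"]["mean"].iloc[0])
        lf_mean = float(cells["LF"]["mean"].iloc[0])
        n_hf = int(cells["HF"]["n"].iloc[0])
        n_lf = int(cells["LF"]["n"].iloc[0])
        if lf_mean == 0:
            pct = math.nan
            logger.warning("LF mean is 0 for %s/%s; response undefined", strain, sex)
        else:
            pct = 100.0 * (hf_mean - lf_mean) / lf_mean
        pval = math.nan
        if have_data and n_hf >= 2 and n_lf >= 2:
            grp = df[(df["strain"] == strain) & (df["sex"] == sex)]
            hf = grp.loc[grp["diet"] == "HF", "y"].to_numpy(float)
            lf = grp.loc[grp["diet"] == "LF", "y"].to_numpy(float)
            pval = float(stats.ttest_ind(hf, lf, equal_var=False).pvalue)
        rows.append(
            {
                "strain": strain,
                "sex": sex,
                "percent_increase": pct,
                "p_value": pval,
                "n_HF": n_hf,
                "n_LF": n_lf,
            }
        )
    return pd.DataFrame(rows)
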