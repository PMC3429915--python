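"""Strain-mean QTL genome scan with interaction models.

The scan regresses strain-sex-diet cohort means (one value per cohort;
strain means are usable as trait values because RI strains are isogenic)
on marker genotype with the factorial model

    Y_ijkl = mu + Sex_i + Diet_j + Genotype_k + Sex x Diet + Sex x Genotype
           + Diet x Genotype + Sex x Diet x Genotype + e_ijkl,

dropping the absent factor and its interactions when scanning a sex, diet
or sex-diet sub-cohort.  The scan statistic is the partial (Type-III) F
of the genotype main effect; evidence is summarised as LOD = log10(1/p).
Because genotype is a two-level factor its partial F equals the squared
t of the sum-coded genotype coefficient, which the implementation
exploits for speed (the permutation oracle re-runs the scan thousands of
times).

QTL are called per chromosome where the peak LOD clears the
chromosome-wide threshold; localisation uses the one-LOD support
interval, bracketed one marker beyond the last qualifying marker on each
side because the true drop point lies between markers.  The additive
genotypic score a is half the difference between the SS-class and
LL-class cohort-mean averages; a > 0 means the SM-derived allele
increases the trait.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("riqtl")

COHORTS = ("all", "F", "M", "HF", "LF", "F:HF", "F:LF", "M:HF", "M:LF")


@dataclass
class ScanResult:
    """Per-marker scan statistics for one analysis cohort."""

    cohort: str
    table: pd.DataFrame  # marker_id, chromosome, position_*, p, lod, a, ...
    skipped: list[tuple[str, str]]  # (marker_id, reason)


@dataclass
class QTLRecord:
    """A called QTL: peak marker, threshold passed, support interval, effect."""

    name: str
    marker_id: str
    chromosome: str
    cohort: str
    lod: float
    additive_effect: float
    threshold: float
    interval: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# Cohort subsetting and design construction
# ---------------------------------------------------------------------------

def cohort_mask(means: pd.DataFrame, cohort: str) -> pd.Series:
    if cohort == "all":
        return pd.Series(True, index=means.index)
    if cohort in ("F", "M"):
        return means["sex"] == cohort
    if cohort in ("HF", "LF"):
        return means["diet"] == cohort
    if ":" in cohort:
        s, d = cohort.split(":")
        return (means["sex"] == s) & (means["diet"] == d)
    raise ValueError(f"unknown cohort {cohort!r}")


def _base_design(sub: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept plus sum-coded sex/diet terms that vary within the cohort."""
    n = len(sub)
    cols = [np.ones(n)]
    names = ["intercept"]
    s = np.where(sub["sex"].to_numpy() == "F", 1.0, -1.0)
    d = np.where(sub["diet"].to_numpy() == "HF", 1.0, -1.0)
    has_sex = sub["sex"].nunique() == 2
    has_diet = sub["diet"].nunique() == 2
    if has_sex:
        cols.append(s)
        names.append("sex")
    if has_diet:
        cols.append(d)
        names.append("diet")
    if has_sex and has_diet:
        cols.append(s * d)
        names.append("sex:diet")
    return np.column_stack(cols), names


def _geno_columns(
    base_names: list[str], base: np.ndarray, g: np.ndarray
) -> tuple[np.ndarray, dict[str, int]]:
    """Append g and its interactions with every base factor column.

    Returns the full design and a name -> column-index map for the
    genotype main effect and its interactions.
    """
    extra = [g]
    colmap = {"geno": base.shape[1]}
    for j, name in enumerate(base_names):
        if name == "intercept":
            continue
        colmap[f"{name}:geno"] = base.shape[1] + len(extra)
        extra.append(base[:, j] * g)
    X = np.column_stack([base] + extra)
    return X, colmap


def _partial_f_1df(X: np.ndarray, y: np.ndarray, col: int) -> tuple[float, float, int]:
    """Partial F (= squared t) and p for one design column, via normal equations."""
    n, p = X.shape
    df_resid = n - p
    if df_resid <= 0:
        return math.nan, math.nan, df_resid
    xtx = X.T @ X
    xty = X.T @ y
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return math.nan, math.nan, df_resid
    beta = xtx_inv @ xty
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / df_resid
    var_b = sigma2 * xtx_inv[col, col]
    if var_b <= 0:
        return math.inf, 0.0, df_resid
    f = float(beta[col] ** 2 / var_b)
    return f, float(stats.f.sf(f, 1, df_resid)), df_resid


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def scan(
    means: pd.DataFrame,
    geno,
    cohort: str = "all",
    min_class_strains: int = 3,
    position_col: str | None = None,
) -> ScanResult:
    """Per-marker genotype partial-F scan on cohort means.

    ``means`` is the cohort-mean table (strain, sex, diet, mean, n);
    ``geno`` a GenotypeMatrix.  Cohort means are weighted equally.
    Markers where fewer than ``min_class_strains`` scanned strains carry
    the minor genotype class are skipped with a logged reason; strains
    with a missing call at a marker drop out of that marker's fit only.
    """
    sub = means.loc[cohort_mask(means, cohort)].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no cohort means for cohort {cohort!r}")
    y = sub["mean"].to_numpy(float)
    base, base_names = _base_design(sub)
    signed = geno.signed()
    row_strains = sub["strain"].to_numpy()
    scanned = [s for s in signed.index if s in set(row_strains)]
    mt = geno.map.table.set_index("marker_id")
    if position_col is None:
        position_col = "position_Mb" if "position_Mb" in mt.columns else "position_cM"

    strain_mean_full = sub.groupby("strain")["mean"].mean()
    rows = []
    skipped: list[tuple[str, str]] = []
    fvals: list[float] = []
    dfs: list[int] = []
    for marker in signed.columns:
        g_strain = signed[marker]
        classes = g_strain.loc[scanned].dropna()
        n_ss = int((classes > 0).sum())
        n_ll = int((classes < 0).sum())
        if n_ss == 0 or n_ll == 0:
            skipped.append((marker, "monomorphic among scanned strains"))
            continue
        if min(n_ss, n_ll) < min_class_strains:
            skipped.append(
                (marker, f"minor genotype class in {min(n_ss, n_ll)} strains")
            )
            continue
        g_row = g_strain.reindex(row_strains).to_numpy(float)
        keep = np.isfinite(g_row)
        X, colmap = _geno_columns(base_names, base[keep], g_row[keep])
        f, _, df_resid = _partial_f_1df(X, y[keep], colmap["geno"])
        # interaction p-values where the model includes them
        p_sg = p_dg = math.nan
        if "sex:geno" in colmap:
            p_sg = _drop_col_p(X, y[keep], colmap["sex:geno"])
        if "diet:geno" in colmap:
            p_dg = _drop_col_p(X, y[keep], colmap["diet:geno"])
        strain_mean = (
            strain_mean_full if keep.all() else sub.loc[keep].groupby("strain")["mean"].mean()
        )
        a = 0.5 * (
            strain_mean.reindex(classes.index[classes > 0]).dropna().mean()
            - strain_mean.reindex(classes.index[classes < 0]).dropna().mean()
        )
        rows.append(
            {
                "marker_id": marker,
                "chromosome": str(mt.loc[marker, "chromosome"]),
                "position": float(mt.loc[marker, position_col]),
                "a": float(a),
                "p_sex_geno": p_sg,
                "p_diet_geno": p_dg,
                "n_strains_LL": n_ll,
                "n_strains_SS": n_ss,
            }
        )
        fvals.append(f)
        dfs.append(df_resid)

    table = pd.DataFrame(rows)
    if len(table):
        f_arr = np.asarray(fvals)
        df_arr = np.asarray(dfs)
        with np.errstate(invalid="ignore"):
            p_arr = stats.f.sf(f_arr, 1, df_arr)
        p_arr = np.clip(p_arr, np.finfo(float).tiny, 1.0)
        table["F"] = f_arr
        table["p"] = p_arr
        table["lod"] = -np.log10(p_arr)
        table = table[
            [
                "marker_id",
                "chromosome",
                "position",
                "F",
                "p",
                "lod",
                "a",
                "p_sex_geno",
                "p_diet_geno",
                "n_strains_LL",
                "n_strains_SS",
            ]
        ]
    if skipped:
        logger.info(
            "scan cohort %s: skipped %d/%d markers (first: %s)",
            cohort,
            len(skipped),
            len(signed.columns),
            skipped[0],
        )
    if not len(table):
        logger.warning("scan cohort %s: no testable markers", cohort)
    return ScanResult(cohort=cohort, table=table, skipped=skipped)


def _drop_col_p(X: np.ndarray, y: np.ndarray, col: int) -> float:
    f, p, _ = _partial_f_1df(X, y, col)
    return p


def additive_effect(means: pd.DataFrame, geno, marker: str, cohort: str = "all") -> float:
    """Additive genotypic score a = (SS-class mean - LL-class mean) / 2.

    Class means average the per-strain cohort-mean averages within the
    analysis cohort; a > 0 means the SM-derived allele raises the trait.
    """
    sub = means.loc[cohort_mask(means, cohort)]
    g = geno.signed()[marker]
    strain_mean = sub.groupby("strain")["mean"].mean()
    g = g.reindex(strain_mean.index).dropna()
    ss = strain_mean.loc[g.index[g > 0]]
    ll = strain_mean.loc[g.index[g < 0]]
    if ss.empty or ll.empty:
        logger.warning("marker %s: one genotype class absent; a undefined", marker)
        return math.nan
    return float((ss.mean() - ll.mean()) / 2.0)


def call_qtls(
    scan_result: ScanResult,
    thresholds,
    trait_tag: str = "QTL",
    with_intervals: bool = True,
    bracketing: bool = True,
) -> list[QTLRecord]:
    """Call at most one QTL per chromosome where peak LOD clears its threshold.

    ``thresholds`` is a ThresholdSet (per-chromosome LOD thresholds).
    Ties at the peak break toward the lower position.  Names follow the
    trait-plus-chromosome convention (e.g. tag "NAFLD" on chromosome 11
    gives "NAFLD11").
    """
    records: list[QTLRecord] = []
    t = scan_result.table
    if t.empty:
        return records
    for chrom, sub in t.groupby("chromosome", sort=False):
        sub = sub.sort_values("position")
        thr = thresholds.chromosome_lod(chrom)
        peak_lod = sub["lod"].max()
        if not np.isfinite(peak_lod) or peak_lod < thr:
            continue
        peak = sub.loc[sub["lod"] == peak_lod].iloc[0]  # sorted -> lowest position
        if (sub["lod"] == peak_lod).sum() > 1:
            logger.info("chromosome %s: peak LOD tie broken to lowest position", chrom)
        rec = QTLRecord(
            name=f"{trait_tag}{chrom}",
            marker_id=str(peak["marker_id"]),
            chromosome=str(chrom),
            cohort=scan_result.cohort,
            lod=float(peak_lod),
            additive_effect=float(peak["a"]),
            threshold=float(thr),
        )
        if with_intervals:
            rec.interval = support_interval(scan_result, rec, bracketing=bracketing)
        records.append(rec)
    return records


def support_interval(
    scan_result: ScanResult, peak: QTLRecord, bracketing: bool = True
) -> tuple[float, float]:
    """One-LOD-drop support interval around a called peak (~95% coverage).

    Qualifying markers are those contiguous with the peak whose LOD stays
    within one unit of the peak LOD.  With ``bracketing`` (default) the
    interval extends one marker beyond the last qualifying marker on each
    side when one exists, since the true one-LOD crossing lies between
    markers; otherwise the strict qualifying span is returned.
    """
    sub = (
        scan_result.table[scan_result.table["chromosome"] == peak.chromosome]
        .sort_values("position")
        .reset_index(drop=True)
    )
    pos = sub["position"].to_numpy(float)
    lod = sub["lod"].to_numpy(float)
    idx = sub.index[sub["marker_id"] == peak.marker_id]
    if len(idx) == 0:
        raise ValueError(f"peak marker {peak.marker_id!r} not on chromosome {peak.chromosome}")
    i = int(idx[0])
    cut = lod[i] - 1.0
    lo = i
    while lo > 0 and lod[lo - 1] >= cut:
        lo -= 1
    hi = i
    while hi < len(lod) - 1 and lod[hi + 1] >= cut:
        hi += 1
    if bracketing:
        lo = max(lo - 1, 0)
        hi = min(hi + 1, len(lod) - 1)
    return float(pos[lo]), float(pos[hi])
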