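"""Multiple-testing thresholds for the genome scan.

Markers on a chromosome are correlated (linkage), so a raw Bonferroni
correction over the marker count is too severe.  The effective number of
independent tests (Meff) is estimated from the eigenvalues of the marker
correlation matrix: each eigenvalue lambda >= 0 contributes

    f(lambda) = I(lambda >= 1) + (lambda - floor(lambda)),

so M independent markers give Meff = M and M perfect copies of one marker
give Meff = 1.  The chromosome-wide point-wise significance level is the
Sidak-adjusted alpha_c = 1 - (1 - alpha)^(1/Meff), reported on the LOD
scale as log10(1/alpha_c); the genome-wide level sums Meff over
chromosomes (inter-chromosomal genotypes assort independently in an RI
panel).  A strain-label permutation oracle provides an empirical check of
these analytic thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import qtlscan

logger = logging.getLogger("riqtl")


@dataclass
class ThresholdSet:
    """Per-chromosome and genome-wide significance thresholds."""

    alpha: float
    per_chromosome: pd.DataFrame  # chromosome, M, meff, p_threshold, lod_threshold
    genome_meff: float
    genome_p_threshold: float
    genome_lod_threshold: float

    def chromosome_lod(self, chromosome: str) -> float:
        t = self.per_chromosome
        row = t.loc[t["chromosome"] == str(chromosome)]
        if row.empty:
            raise KeyError(f"no threshold for chromosome {chromosome!r}")
        return float(row["lod_threshold"].iloc[0])

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "chromosomes": self.per_chromosome.to_dict(orient="records"),
            "genome": {
                "meff": self.genome_meff,
                "p_threshold": self.genome_p_threshold,
                "lod_threshold": self.genome_lod_threshold,
            },
        }


def _meff_from_eigenvalues(lam: np.ndarray) -> float:
    # round away eigensolver noise so exact duplicates give integer eigenvalues
    lam = np.round(lam[lam > 1e-10], 8)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def li_ji_meff(geno, chromosome: str, min_pair_obs: int = 4) -> float:
    """Effective number of independent tests for one chromosome's markers.

    Genotypes are coded +/-1 and correlated across strains with
    pairwise-complete observations; Meff applies the integer/fractional
    eigenvalue partition to the correlation spectrum.  Monomorphic markers
    carry no test and are excluded; an entirely monomorphic chromosome is
    rejected.
    """
    markers = geno.markers_on(chromosome)
    if not markers:
        raise ValueError(f"no markers on chromosome {chromosome!r}")
    signed = geno.signed()[markers]
    poly = [m for m in markers if signed[m].dropna().nunique() >= 2]
    if not poly:
        raise ValueError(f"chromosome {chromosome!r} is monomorphic")
    if len(poly) < len(markers):
        logger.info(
            "chromosome %s: %d monomorphic markers excluded from Meff",
            chromosome,
            len(markers) - len(poly),
        )
    sub = signed[poly]
    n_pairs = sub.notna().astype(int).T @ sub.notna().astype(int)
    if (n_pairs.to_numpy() < min_pair_obs).any():
        logger.warning(
            "chromosome %s: some marker pairs have < %d complete observations",
            chromosome,
            min_pair_obs,
        )
    corr = sub.corr(method="pearson")  # pairwise-complete
    c = corr.to_numpy()
    if not np.all(np.isfinite(c)):
        raise ValueError(f"chromosome {chromosome!r}: undefined marker correlations")
    trace = float(np.trace(c))
    if not math.isclose(trace, len(poly), rel_tol=1e-9, abs_tol=1e-9):
        raise AssertionError(f"correlation trace {trace} != {len(poly)}")
    lam = np.linalg.eigvalsh(c)
    return _meff_from_eigenvalues(lam)


def significance_thresholds(
    meffs: dict[str, float],
    alpha: float = 0.05,
    marker_counts: dict[str, int] | None = None,
    method: str = "sidak",
) -> ThresholdSet:
    """Chromosome- and genome-wide thresholds from per-chromosome Meff.

    The point-wise p threshold is Sidak 1-(1-alpha)^(1/Meff) by default
    (``method="bonferroni"`` uses alpha/Meff; the two are nearly identical
    at alpha = 0.05).  The genome-wide threshold uses the summed Meff.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")

    def point_alpha(meff: float) -> float:
        if method == "sidak":
            return 1.0 - (1.0 - alpha) ** (1.0 / meff)
        if method == "bonferroni":
            return alpha / meff
        raise ValueError(f"unknown method {method!r}")

    rows = []
    for chrom, meff in meffs.items():
        a_c = point_alpha(meff)
        rows.append(
            {
                "chromosome": str(chrom),
                "M": int(marker_counts[chrom]) if marker_counts else None,
                "meff": float(meff),
                "p_threshold": a_c,
                "lod_threshold": -math.log10(a_c),
            }
        )
    meff_total = float(sum(meffs.values()))
    a_g = point_alpha(meff_total)
    return ThresholdSet(
        alpha=alpha,
        per_chromosome=pd.DataFrame(rows),
        genome_meff=meff_total,
        genome_p_threshold=a_g,
        genome_lod_threshold=-math.log10(a_g),
    )


def thresholds_for_panel(geno, alpha: float = 0.05, method: str = "sidak") -> ThresholdSet:
    """Li & Ji thresholds for every chromosome of a genotype matrix."""
    meffs: dict[str, float] = {}
    counts: dict[str, int] = {}
    for chrom in geno.map.chromosomes:
        try:
            meffs[chrom] = li_ji_meff(geno, chrom)
        except ValueError as e:
            logger.warning("chromosome %s skipped: %s", chrom, e)
            continue
        counts[chrom] = len(geno.markers_on(chrom))
    return significance_thresholds(meffs, alpha, counts, method)


def permutation_threshold(
    means: pd.DataFrame,
    geno,
    cohort: str,
    n_perm: int,
    seed: int,
    alpha: float = 0.05,
    chromosome: str | None = None,
    min_class_strains: int = 3,
) -> float:
    """Empirical max-LOD threshold by permuting strain labels of the genotypes.

    Breaks the genotype-phenotype link while preserving marker-marker
    correlation, giving a null distribution of the per-permutation maximum
    LOD over the chromosome (or the genome when ``chromosome`` is None).
    Returns the ceil((1-alpha) n_perm)-th order statistic.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    k = math.ceil((1.0 - alpha) * n_perm)
    if k >= n_perm:
        logger.warning("n_perm=%d too small for alpha=%.3g quantile", n_perm, alpha)

    sub = means.loc[qtlscan.cohort_mask(means, cohort)].reset_index(drop=True)
    y = sub["mean"].to_numpy(float)
    base, base_names = qtlscan._base_design(sub)
    signed = geno.signed()
    if chromosome is not None:
        signed = signed[geno.markers_on(chromosome)]
    strains = list(signed.index)
    G = signed.to_numpy(float)  # strain x marker
    row_of_strain = {s: i for i, s in enumerate(strains)}
    row_idx = np.array([row_of_strain[s] for s in sub["strain"]])

    # drop markers that would be skipped by the unpermuted scan
    keep_cols = []
    scanned = sorted(set(sub["strain"]) & set(strains))
    scan_rows = np.array([row_of_strain[s] for s in scanned])
    for j in range(G.shape[1]):
        col = G[scan_rows, j]
        col = col[np.isfinite(col)]
        n_ss = int((col > 0).sum())
        n_ll = int((col < 0).sum())
        if n_ss and n_ll and min(n_ss, n_ll) >= min_class_strains:
            keep_cols.append(j)
    if not keep_cols:
        raise ValueError("no testable markers for the permutation oracle")
    G = G[:, keep_cols]

    rng = np.random.default_rng(seed)
    from scipy import stats as _st

    max_lods = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(strains))
        Gp = G[perm][row_idx]  # rows aligned to cohort means
        fvals = np.empty(Gp.shape[1])
        dfs = np.empty(Gp.shape[1], dtype=int)
        for j in range(Gp.shape[1]):
            g = Gp[:, j]
            keep = np.isfinite(g)
            X, colmap = qtlscan._geno_columns(base_names, base[keep], g[keep])
            f, _, df_resid = qtlscan._partial_f_1df(X, y[keep], colmap["geno"])
            fvals[j] = f if np.isfinite(f) else 0.0
            dfs[j] = max(df_resid, 1)
        pvals = _st.f.sf(fvals, 1, dfs)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        max_lods[b] = float(np.max(-np.log10(pvals)))
    return float(np.sort(max_lods)[k - 1])
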