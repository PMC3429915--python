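"""Synthetic recombinant-inbred (RI) panel generator.

Emulates a two-parent RI strain panel of the kind used for dietary-response
quantitative genetics in mice: a set of fully inbred strains derived from an
F2 intercross of two parental lines (here labelled LG and SM after the
classical large/small body-size selection lines), genotyped at homozygous
SNP markers across 19 autosomes plus X, and phenotyped for liver fat and
lean mass in a full strain x sex x diet factorial.

Genomes are simulated as independent two-state Markov mosaics along each
chromosome.  The switch probability between adjacent markers is the
RI-expanded recombination fraction for sib-mated lines,

    R = 4r / (1 + 6r),

with the single-meiosis fraction ``r`` obtained from the inter-marker map
distance through Haldane's map function ``r = (1 - exp(-2d/100)) / 2``
(``d`` in cM).

Phenotypes realise the three-way mixed ANOVA generative model: fixed sex,
diet and sex x diet effects, random strain and strain-interaction effects
with configurable variances, optional planted QTL with additive effects
restricted to an analysis scope, and i.i.d. residual noise.  Fat and lean
masses are constructed so that the residual of fat regressed on lean (the
"fattiness" trait) recovers the simulated genetic signal by design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("riqtl")

# Genotype codes: homozygous for the LG-derived or SM-derived allele.
LL = "LL"
SS = "SS"
MISSING = "NA"

SEXES = ("F", "M")
DIETS = ("HF", "LF")

#: analysis cohorts used throughout the pipeline
ALL_COHORTS = ("all", "F", "M", "HF", "LF", "F:HF", "F:LF", "M:HF", "M:LF")

PARENTAL_LG = "LG"
PARENTAL_SM = "SM"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker map: id, chromosome label and position in cM.

    Positions must be strictly increasing within each chromosome and marker
    ids unique.  An optional physical position (Mb) column supports
    Mb-scale interval reporting.
    """

    table: pd.DataFrame  # columns: marker_id, chromosome, position_cM [, position_Mb]

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker_id", "chromosome", "position_cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        if t["marker_id"].duplicated().any():
            dupes = t.loc[t["marker_id"].duplicated(), "marker_id"].tolist()
            raise ValueError(f"duplicate marker ids: {dupes[:5]}")
        for chrom, sub in t.groupby("chromosome", sort=False):
            pos = sub["position_cM"].to_numpy(float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
            if np.any(pos < 0):
                raise ValueError(f"negative position on chromosome {chrom}")

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.table["chromosome"]:
            seen.setdefault(str(c), None)
        return list(seen)

    def chromosome_of(self, marker_id: str) -> str:
        row = self.table.loc[self.table["marker_id"] == marker_id]
        if row.empty:
            raise KeyError(f"unknown marker {marker_id!r}")
        return str(row["chromosome"].iloc[0])

    def __len__(self) -> int:
        return len(self.table)


def default_marker_map(
    n_markers: int = 512,
    chromosomes: Sequence[str] | None = None,
    chrom_length_cM: float = 80.0,
) -> MarkerMap:
    """Evenly spaced grid of markers over 19 autosomes + X.

    The true spacing of an informative RI SNP panel is platform-specific;
    an even per-chromosome grid is the neutral default.  Markers are split
    as evenly as possible across chromosomes.
    """
    if chromosomes is None:
        chromosomes = [str(i) for i in range(1, 20)] + ["X"]
    n_chrom = len(chromosomes)
    base, extra = divmod(n_markers, n_chrom)
    rows = []
    for i, chrom in enumerate(chromosomes):
        m = base + (1 if i < extra else 0)
        # even spacing with a margin at both telomeres
        pos = np.linspace(0.0, chrom_length_cM, m + 2)[1:-1]
        for j in range(m):
            rows.append(
                {
                    "marker_id": f"m{chrom}_{j + 1:03d}",
                    "chromosome": chrom,
                    "position_cM": round(float(pos[j]), 4),
                    "position_Mb": round(float(pos[j]) * 2.0, 4),  # ~2 Mb/cM
                }
            )
    return MarkerMap(pd.DataFrame(rows))


@dataclass(frozen=True)
class GenotypeMatrix:
    """Strain x marker matrix of homozygous parental-origin calls.

    ``calls`` is indexed by strain, with one column per marker id in map
    order; values are "LL", "SS" or "NA".  Heterozygous codes are illegal
    for inbred strains and rejected.
    """

    strains: tuple[str, ...]
    map: MarkerMap
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.to_numpy())) - {LL, SS, MISSING}
        if bad:
            raise ValueError(
                f"illegal genotype codes {sorted(bad)}; RI strains are homozygous"
            )
        if list(self.calls.index) != list(self.strains):
            raise ValueError("calls index does not match strain list")
        if list(self.calls.columns) != self.map.marker_ids:
            raise ValueError("calls columns do not match marker map order")

    @property
    def missing_rate(self) -> float:
        return float((self.calls.to_numpy() == MISSING).mean())

    def signed(self) -> pd.DataFrame:
        """Numeric coding LL -> -1, SS -> +1, missing -> NaN."""
        arr = self.calls.to_numpy(dtype=object)
        out = np.full(arr.shape, np.nan)
        out[arr == LL] = -1.0
        out[arr == SS] = 1.0
        return pd.DataFrame(out, index=self.calls.index, columns=self.calls.columns)

    def markers_on(self, chromosome: str) -> list[str]:
        t = self.map.table
        return t.loc[t["chromosome"].astype(str) == str(chromosome), "marker_id"].tolist()


@dataclass
class QTLSpec:
    """A planted additive QTL: ``+a`` for SS strains, ``-a`` for LL strains.

    ``scope`` restricts the effect to an analysis cohort: "all", a sex
    ("F"/"M"), a diet ("HF"/"LF"), or a sex-diet cell ("F:HF", ...).
    """

    marker_id: str
    additive_effect: float
    scope: str = "all"

    def applies(self, sex: str, diet: str) -> bool:
        if self.scope == "all":
            return True
        if self.scope in SEXES:
            return sex == self.scope
        if self.scope in DIETS:
            return diet == self.scope
        if ":" in self.scope:
            s, d = self.scope.split(":")
            return sex == s and diet == d
        raise ValueError(f"unknown QTL scope {self.scope!r}")


@dataclass
class SimulationConfig:
    """Parameters of the factorial phenotype model.

    Variances are on the scale of the fattiness trait; defaults give
    heritabilities of roughly 22% (strain), 17% (diet x strain),
    12% (sex x strain) and 9% (three-way) against a unit residual, the
    regime typical of diet-responsive liver fat in RI mouse panels.
    """

    n_ri_strains: int = 16
    include_parentals: bool = True
    cohort_n: int | Mapping[tuple[str, str, str], int] = 7
    var_strain: float = 0.282
    var_sexstrain: float = 0.136
    var_dietstrain: float = 0.205
    var_sexdietstrain: float = 0.099
    var_residual: float = 1.0
    fixed_sex_effect: float = 0.3   # F minus M, half-difference applied +/-
    fixed_diet_effect: float = 0.5  # HF minus LF, half-difference applied +/-
    fixed_sexdiet_effect: float = 0.15
    qtls: list[QTLSpec] = field(default_factory=list)
    grand_mean: float = 0.0
    lean_mean: float = 800.0   # mg
    lean_sd: float = 80.0      # mg
    fat_slope: float = 0.5     # fat = slope * lean + trait + offset
    fat_offset: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "var_strain",
            "var_sexstrain",
            "var_dietstrain",
            "var_sexdietstrain",
            "var_residual",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_ri_strains < 1:
            raise ValueError("n_ri_strains must be >= 1")
        if isinstance(self.cohort_n, int) and self.cohort_n < 1:
            raise ValueError("cohort_n must be >= 1")

    def strain_names(self) -> list[str]:
        names = [f"RI{i + 1:02d}" for i in range(self.n_ri_strains)]
        if self.include_parentals:
            names = names + [PARENTAL_LG, PARENTAL_SM]
        return names

    def cell_n(self, strain: str, sex: str, diet: str) -> int:
        if isinstance(self.cohort_n, int):
            return self.cohort_n
        return int(self.cohort_n.get((strain, sex, diet), 0))


# ---------------------------------------------------------------------------
# Map-expansion arithmetic
# ---------------------------------------------------------------------------

def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Single-meiosis recombination fraction from map distance (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, float) / 100.0))


def ri_expanded_R(r: np.ndarray | float) -> np.ndarray | float:
    """RI-panel switch probability for sib-mated lines: R = 4r/(1+6r)."""
    r = np.asarray(r, float)
    return 4.0 * r / (1.0 + 6.0 * r)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def simulate_ri_genomes(
    marker_map: MarkerMap,
    n_strains: int,
    seed: int,
    include_parentals: bool = False,
    missing_rate: float = 0.0,
    strain_names: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Simulate RI strain genotypes as chromosome-wise Markov mosaics.

    Each strain and chromosome is an independent two-state chain over the
    ordered markers: the first marker is LL or SS with probability 1/2 and
    each adjacent pair switches state with probability ``4r/(1+6r)`` where
    ``r`` comes from the cM gap via Haldane's map function.  Parental
    strains, when requested, are appended as all-LL (LG) and all-SS (SM).
    """
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    if strain_names is None:
        strain_names = [f"RI{i + 1:02d}" for i in range(n_strains)]
    elif len(strain_names) != n_strains:
        raise ValueError("strain_names length mismatch")

    t = marker_map.table
    blocks: list[np.ndarray] = []
    col_order: list[str] = []
    for chrom, sub in t.groupby("chromosome", sort=False):
        pos = sub["position_cM"].to_numpy(float)
        col_order.extend(sub["marker_id"].tolist())
        m = len(pos)
        R = ri_expanded_R(haldane_r(np.diff(pos)))
        states = np.empty((n_strains, m), dtype=np.int8)
        states[:, 0] = rng.integers(0, 2, size=n_strains)
        if m > 1:
            switches = rng.random((n_strains, m - 1)) < R[None, :]
            # cumulative XOR of switch indicators propagates the chain
            states[:, 1:] = (
                states[:, [0]] + np.cumsum(switches.astype(np.int8), axis=1)
            ) % 2
        blocks.append(states)

    numeric = np.concatenate(blocks, axis=1)
    calls = np.where(numeric == 0, LL, SS).astype(object)

    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        # keep >=1 non-missing call per strain per chromosome
        calls[mask] = MISSING

    if include_parentals:
        lg = np.full((1, calls.shape[1]), LL, dtype=object)
        sm = np.full((1, calls.shape[1]), SS, dtype=object)
        calls = np.vstack([calls, lg, sm])
        strain_names = list(strain_names) + [PARENTAL_LG, PARENTAL_SM]

    frame = pd.DataFrame(calls, index=list(strain_names), columns=col_order)
    # restore the original map column order (groupby preserved it, but be safe)
    frame = frame[marker_map.marker_ids]
    geno = GenotypeMatrix(tuple(strain_names), marker_map, frame)
    logger.info(
        "simulated %d strains x %d markers (missing rate %.3f)",
        len(strain_names),
        len(marker_map),
        geno.missing_rate,
    )
    return geno


def _fixed_effect(sex: str, diet: str, cfg: SimulationConfig) -> float:
    s = 0.5 if sex == "F" else -0.5
    d = 0.5 if diet == "HF" else -0.5
    return (
        cfg.fixed_sex_effect * s
        + cfg.fixed_diet_effect * d
        + cfg.fixed_sexdiet_effect * (2 * s) * (2 * d) * 0.5
    )


def simulate_phenotypes(geno: GenotypeMatrix, cfg: SimulationConfig) -> pd.DataFrame:
    """Draw a factorial phenotype table from the three-way ANOVA model.

    Each animal's latent trait value is

        mu + sex + diet + sex*diet
           + strain + sex*strain + diet*strain + sex*diet*strain
           + sum of in-scope QTL contributions (+/- a by genotype class)
           + residual,

    with the random effects drawn once per strain (or strain-by-factor
    cell) from centred normals with the configured variances.  Fat and
    lean masses are then constructed so that regressing fat on lean
    returns this latent value as the residual: lean is drawn from a
    positive normal and ``fat = slope * lean + value + offset`` (clipped
    at zero with a warning, which would distort residuals).

    Returns a phenotype table with one row per animal and columns
    ``animal_id, strain, sex, diet, fat_mg, lean_mg``.
    """
    strains = [s for s in cfg.strain_names() if s in geno.strains]
    if len(strains) != len(cfg.strain_names()):
        missing = set(cfg.strain_names()) - set(geno.strains)
        raise ValueError(f"genotypes missing for strains {sorted(missing)}")
    for q in cfg.qtls:
        if q.marker_id not in geno.calls.columns:
            raise ValueError(f"QTL marker {q.marker_id!r} not in genotype matrix")

    rng = np.random.default_rng(cfg.seed)
    n_str = len(strains)

    strain_eff = dict(zip(strains, rng.normal(0, np.sqrt(cfg.var_strain), n_str)))
    sexstr_eff = {
        (s, x): v
        for (s, x), v in zip(
            [(s, x) for s in strains for x in SEXES],
            rng.normal(0, np.sqrt(cfg.var_sexstrain), n_str * 2),
        )
    }
    dietstr_eff = {
        (s, d): v
        for (s, d), v in zip(
            [(s, d) for s in strains for d in DIETS],
            rng.normal(0, np.sqrt(cfg.var_dietstrain), n_str * 2),
        )
    }
    sexdietstr_eff = {
        (s, x, d): v
        for (s, x, d), v in zip(
            [(s, x, d) for s in strains for x in SEXES for d in DIETS],
            rng.normal(0, np.sqrt(cfg.var_sexdietstrain), n_str * 4),
        )
    }

    signed = geno.signed()
    rows = []
    clipped = 0
    aid = 0
    for strain in strains:
        for sex in SEXES:
            for diet in DIETS:
                n = cfg.cell_n(strain, sex, diet)
                if n == 0:
                    continue
                base = (
                    cfg.grand_mean
                    + _fixed_effect(sex, diet, cfg)
                    + strain_eff[strain]
                    + sexstr_eff[(strain, sex)]
                    + dietstr_eff[(strain, diet)]
                    + sexdietstr_eff[(strain, sex, diet)]
                )
                for q in cfg.qtls:
                    if q.applies(sex, diet):
                        g = signed.at[strain, q.marker_id]
                        if np.isfinite(g):
                            base += q.additive_effect * g
                resid = rng.normal(0, np.sqrt(cfg.var_residual), n)
                lean = np.abs(rng.normal(cfg.lean_mean, cfg.lean_sd, n))
                value = base + resid
                fat = cfg.fat_slope * lean + value + cfg.fat_offset
                neg = fat < 0
                clipped += int(neg.sum())
                fat = np.clip(fat, 0.0, None)
                for k in range(n):
                    aid += 1
                    rows.append(
                        {
                            "animal_id": f"a{aid:04d}",
                            "strain": strain,
                            "sex": sex,
                            "diet": diet,
                            "fat_mg": float(fat[k]),
                            "lean_mg": float(lean[k]),
                        }
                    )
    if clipped:
        warnings.warn(
            f"{clipped} fat masses clipped at 0; residual trait is distorted "
            "for those animals (raise fat_offset or grand_mean)",
            RuntimeWarning,
            stacklevel=2,
        )
    pheno = pd.DataFrame(rows)
    logger.info("simulated %d animals over %d strains", len(pheno), n_str)
    return pheno


def validate_phenotypes(pheno: pd.DataFrame) -> None:
    """Invariant checks shared by the simulator and the CSV reader."""
    required = {"animal_id", "strain", "sex", "diet", "fat_mg", "lean_mg"}
    missing = required - set(pheno.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    if not set(pheno["sex"]).issubset(set(SEXES)):
        raise ValueError("sex must be F or M")
    if not set(pheno["diet"]).issubset(set(DIETS)):
        raise ValueError("diet must be HF or LF")
    fat = pheno["fat_mg"].to_numpy(float)
    lean = pheno["lean_mg"].to_numpy(float)
    if not np.all(np.isfinite(fat)) or not np.all(np.isfinite(lean)):
        raise ValueError("non-finite mass values")
    if np.any(fat < 0):
        bad = pheno.index[fat < 0].tolist()
        raise ValueError(f"negative fat mass at rows {bad[:5]}")
    if np.any(lean <= 0):
        bad = pheno.index[lean <= 0].tolist()
        raise ValueError(f"non-positive lean mass at rows {bad[:5]}")
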