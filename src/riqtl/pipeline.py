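"""End-to-end orchestration: simulate/load -> traits -> ANOVA -> thresholds -> scan.

``run_pipeline`` executes the full analysis on either a simulated panel or
files on disk and returns a :class:`RunReport` bundling every stage's
output.  All randomness flows from the single config seed, so a report is
reproducible byte-identically from (config, seed, inputs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as rio
from . import qtlscan, thresholds as thr, traits as tr, varcomp as vc
from .simgen import (
    SimulationConfig,
    default_marker_map,
    simulate_phenotypes,
    simulate_ri_genomes,
)

logger = logging.getLogger("riqtl")

DEFAULT_COHORTS = ("all", "F", "M", "HF", "LF", "F:HF", "F:LF", "M:HF", "M:LF")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of (``geno_path``+``map_path``+``pheno_path``) or ``sim``
    must be provided.
    """

    sim: SimulationConfig | None = None
    marker_map: "object | None" = None  # MarkerMap for simulation; default 512-SNP grid
    geno_path: str | None = None
    map_path: str | None = None
    pheno_path: str | None = None
    cohorts: tuple[str, ...] = DEFAULT_COHORTS
    alpha: float = 0.05
    trait: str = "fattiness_residual"  # or "percent_fat"
    trait_tag: str = "QTL"
    per_cohort_regression: bool = False
    threshold_method: str = "sidak"
    bracketing: bool = True
    min_class_strains: int = 3
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        from_files = all(
            p is not None for p in (self.geno_path, self.map_path, self.pheno_path)
        )
        if from_files == (self.sim is not None):
            raise ValueError(
                "provide exactly one of a simulation block or input file paths"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.trait not in ("fattiness_residual", "percent_fat"):
            raise ValueError(f"unknown trait {self.trait!r}")


@dataclass
class RunReport:
    """Everything one pipeline run computed, plus provenance."""

    config: dict
    seed: int
    version: str
    anova: pd.DataFrame
    varcomp: vc.VarianceComponentsResult
    genetic_correlations: dict
    dietary_response: pd.DataFrame
    cohort_means: pd.DataFrame
    thresholds: thr.ThresholdSet
    scans: dict[str, qtlscan.ScanResult]
    qtls: list[qtlscan.QTLRecord] = field(default_factory=list)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def _config_echo(cfg: RunConfig) -> dict:
    d = dict(vars(cfg))
    if cfg.sim is not None:
        sim = dict(vars(cfg.sim))
        sim["qtls"] = [vars(q) for q in cfg.sim.qtls]
        if not isinstance(sim["cohort_n"], int):
            sim["cohort_n"] = {
                "|".join(k): v for k, v in dict(sim["cohort_n"]).items()
            }
        d["sim"] = sim
    d["cohorts"] = list(cfg.cohorts)
    if cfg.marker_map is not None:
        d["marker_map"] = f"custom({len(cfg.marker_map)} markers)"
    return d


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full analysis and return the report.

    Stages: simulate or load the panel; derive the analysis trait; cohort
    means; three-way ANOVA with variance components and heritabilities;
    genetic correlations (between-diet for the trait, plus any extra
    phenotype columns); per-strain dietary response on percent fat;
    Li & Ji thresholds; per-cohort genome scans; QTL calls with one-LOD
    support intervals.
    """
    # --- inputs ------------------------------------------------------------
    if cfg.sim is not None:
        sim = cfg.sim
        mm = cfg.marker_map if cfg.marker_map is not None else default_marker_map()
        geno = simulate_ri_genomes(
            mm,
            sim.n_ri_strains,
            seed=sim.seed,
            include_parentals=sim.include_parentals,
            missing_rate=sim.missing_rate,
        )
        pheno = simulate_phenotypes(geno, sim)
    else:
        geno = _stage("read_genotypes")(rio.read_genotypes)(cfg.geno_path, cfg.map_path)
        pheno = _stage("read_phenotypes")(rio.read_phenotypes)(cfg.pheno_path)
        unknown = set(pheno["strain"]) - set(geno.strains)
        if unknown:
            raise RuntimeError(
                f"pipeline stage 'read_phenotypes' failed: phenotype strains "
                f"{sorted(unknown)} absent from genotype matrix"
            )
    logger.info("panel: %d strains, %d markers, %d animals",
                len(geno.strains), len(geno.map), len(pheno))

    # --- traits ------------------------------------------------------------
    if cfg.trait == "fattiness_residual":
        trait = _stage("traits")(tr.compute_fattiness)(
            pheno, per_cohort=cfg.per_cohort_regression
        )
    else:
        trait = _stage("traits")(tr.percent_fat)(pheno)
    pct = tr.percent_fat(pheno)
    means = _stage("cohort_means")(tr.cohort_means)(trait, pheno)

    # --- variance components ------------------------------------------------
    anova = _stage("anova")(vc.anova_three_way)(trait, pheno)
    comps = _stage("varcomp")(vc.variance_components)(anova, pheno)
    for sex in ("F", "M"):
        for diet in ("HF", "LF"):
            try:
                comps.H2_by_cohort[f"{sex}:{diet}"] = vc.heritability_by_cohort(
                    trait, pheno, sex, diet
                )
            except ValueError as e:
                logger.warning("cohort H2 %s:%s unavailable: %s", sex, diet, e)

    # --- genetic correlations ----------------------------------------------
    correlations: dict = {}
    by_diet = vc.strain_means(trait, pheno, by=("diet",))
    if {"HF", "LF"}.issubset(by_diet.columns):
        r, r2 = vc.genetic_correlation(by_diet["HF"].dropna(), by_diet["LF"].dropna())
        correlations["between_diet"] = {"r": r, "r2": r2}
    overall = vc.strain_means(trait, pheno)
    for col in rio.extra_trait_columns(pheno):
        other = pheno.groupby("strain")[col].mean()
        try:
            r, r2 = vc.genetic_correlation(overall, other)
            correlations[col] = {"r": r, "r2": r2}
        except ValueError as e:
            logger.warning("correlation with %s unavailable: %s", col, e)

    # --- dietary response (percent fat, didactic trait) ---------------------
    pct_means = tr.cohort_means(pct, pheno)
    response = _stage("dietary_response")(tr.dietary_response)(pct_means, pct, pheno)

    # --- thresholds and scans -----------------------------------------------
    tset = _stage("thresholds")(thr.thresholds_for_panel)(
        geno, cfg.alpha, cfg.threshold_method
    )
    scans: dict[str, qtlscan.ScanResult] = {}
    qtls: list[qtlscan.QTLRecord] = []
    for cohort in cfg.cohorts:
        res = _stage(f"scan[{cohort}]")(qtlscan.scan)(
            means, geno, cohort, min_class_strains=cfg.min_class_strains
        )
        scans[cohort] = res
        qtls.extend(
            qtlscan.call_qtls(
                res, tset, trait_tag=cfg.trait_tag, bracketing=cfg.bracketing
            )
        )

    return RunReport(
        config=_config_echo(cfg),
        seed=cfg.seed,
        version=__version__,
        anova=anova,
        varcomp=comps,
        genetic_correlations=correlations,
        dietary_response=response,
        cohort_means=means,
        thresholds=tset,
        scans=scans,
        qtls=qtls,
    )


def format_qtl_table(qtls: list[qtlscan.QTLRecord]) -> str:
    """Plain-text QTL report: name, peak SNP, CI, LOD, a, cohort."""
    header = f"{'QTL':<10}{'SNP':<14}{'CI':<18}{'LOD':>6}{'a':>8}  Cohort"
    lines = [header, "-" * len(header)]
    for q in qtls:
        ci = f"{q.interval[0]:.1f}-{q.interval[1]:.1f}" if q.interval else "NA"
        lines.append(
            f"{q.name:<10}{q.marker_id:<14}{ci:<18}{q.lod:>6.2f}{q.additive_effect:>8.2f}  {q.cohort}"
        )
    return "\n".join(lines)


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Persist every stage's output under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.anova.to_csv(out / "anova.csv")
    report.cohort_means.to_csv(out / "cohort_means.csv", index=False)
    report.dietary_response.to_csv(out / "dietary_response.csv", index=False)
    with open(out / "varcomp.json", "w") as fh:
        json.dump(report.varcomp.as_dict(), fh, indent=2)
    with open(out / "correlations.json", "w") as fh:
        json.dump(report.genetic_correlations, fh, indent=2)
    with open(out / "thresholds.json", "w") as fh:
        json.dump(report.thresholds.as_dict(), fh, indent=2)
    for cohort, res in report.scans.items():
        res.table.to_csv(out / f"scan_{cohort.replace(':', '_')}.csv", index=False)
    with open(out / "qtls.json", "w") as fh:
        json.dump(
            [
                {
                    "name": q.name,
                    "marker_id": q.marker_id,
                    "chromosome": q.chromosome,
                    "cohort": q.cohort,
                    "lod": q.lod,
                    "a": q.additive_effect,
                    "threshold": q.threshold,
                    "interval": list(q.interval) if q.interval else None,
                }
                for q in report.qtls
            ],
            fh,
            indent=2,
        )
    (out / "qtl_report.txt").write_text(format_qtl_table(report.qtls) + "\n")
    with open(out / "run.json", "w") as fh:
        json.dump(
            {"version": report.version, "seed": report.seed, "config": report.config},
            fh,
            indent=2,
            default=str,
        )
    logger.info("report written to %s", out)
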