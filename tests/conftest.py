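import numpy as np
import pandas as pd
import pytest

from riqtl import (
    MarkerMap,
    SimulationConfig,
    simulate_phenotypes,
    simulate_ri_genomes,
)


def two_marker_map(d_cM: float) -> MarkerMap:
    return MarkerMap(
        pd.DataFrame(
            {
                "marker_id": ["mA", "mB"],
                "chromosome": ["1", "1"],
                "position_cM": [0.0, d_cM],
            }
        )
    )


def grid_map(n_chrom: int, per_chrom: int, spacing_cM: float) -> MarkerMap:
    rows = []
    for c in range(1, n_chrom + 1):
        for j in range(per_chrom):
            rows.append(
                {
                    "marker_id": f"m{c}_{j + 1:02d}",
                    "chromosome": str(c),
                    "position_cM": j * spacing_cM,
                    "position_Mb": j * spacing_cM * 2.0,
                }
            )
    return MarkerMap(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_panel():
    """A quiet 16-strain panel: genotypes plus noise-only phenotypes."""
    mm = grid_map(n_chrom=3, per_chrom=8, spacing_cM=10.0)
    geno = simulate_ri_genomes(mm, 16, seed=11)
    cfg = SimulationConfig(
        n_ri_strains=16,
        include_parentals=False,
        cohort_n=6,
        var_strain=0.3,
        var_sexstrain=0.1,
        var_dietstrain=0.2,
        var_sexdietstrain=0.05,
        seed=11,
    )
    pheno = simulate_phenotypes(geno, cfg)
    return mm, geno, pheno, cfg


def genotype_matrix_from_patterns(patterns: dict[str, str]) -> "GenotypeMatrix":
    """Build a one-chromosome GenotypeMatrix from 0/1 strings (1 -> SS)."""
    from riqtl import GenotypeMatrix

    n = len(next(iter(patterns.values())))
    mm = MarkerMap(
        pd.DataFrame(
            {
                "marker_id": list(patterns),
                "chromosome": ["1"] * len(patterns),
                "position_cM": [float(10 * i) for i in range(len(patterns))],
            }
        )
    )
    strains = [f"S{i + 1}" for i in range(n)]
    calls = pd.DataFrame(
        {
            m: ["SS" if ch == "1" else "LL" for ch in pat]
            for m, pat in patterns.items()
        },
        index=strains,
    )
    return GenotypeMatrix(tuple(strains), mm, calls[mm.marker_ids])
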