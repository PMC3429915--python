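"""CSV dialects and validated readers/writers for panel data.

All files are plain comma-separated UTF-8 with a header row; missing
values are "NA".  Three files describe a panel:

* marker map — ``marker_id,chromosome,position_cM[,position_Mb]``
* genotypes  — rows = strains (first column ``strain``), one column per
  marker, values ``LL``/``SS``/``NA``
* phenotypes — ``animal_id,strain,sex,diet,fat_mg,lean_mg`` plus any
  extra numeric trait columns

Readers enforce the panel invariants (homozygous-only calls, unique
markers, positive masses) and report the offending row/column, so a
write/read round trip is the identity on valid objects.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .simgen import LL, MISSING, SS, GenotypeMatrix, MarkerMap, validate_phenotypes

logger = logging.getLogger("riqtl")

NA = "NA"


def write_marker_map(mm: MarkerMap, path: str | Path) -> None:
    mm.table.to_csv(path, index=False, na_rep=NA)


def read_marker_map(path: str | Path) -> MarkerMap:
    t = pd.read_csv(path, na_values=[NA], keep_default_na=False)
    t["chromosome"] = t["chromosome"].astype(str)
    return MarkerMap(t)


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    out = geno.calls.copy()
    out.index.name = "strain"
    out.to_csv(path, na_rep=NA)


def read_genotypes(geno_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    mm = read_marker_map(map_path)
    t = pd.read_csv(geno_path, dtype=str, na_values=[], keep_default_na=False)
    if "strain" not in t.columns:
        raise ValueError(f"{geno_path}: first column must be 'strain'")
    t = t.set_index("strain")
    extra = set(t.columns) - set(mm.marker_ids)
    missing = set(mm.marker_ids) - set(t.columns)
    if extra or missing:
        raise ValueError(
            f"{geno_path}: genotype columns do not match marker map "
            f"(extra {sorted(extra)[:3]}, missing {sorted(missing)[:3]})"
        )
    arr = t.to_numpy(dtype=object)
    legal = {LL, SS, MISSING}
    for i, strain in enumerate(t.index):
        for j, marker in enumerate(t.columns):
            if arr[i, j] not in legal:
                raise ValueError(
                    f"{geno_path}: illegal genotype code {arr[i, j]!r} at "
                    f"strain {strain!r}, marker {marker!r} "
                    "(heterozygotes are illegal for inbred strains)"
                )
    calls = t[mm.marker_ids]
    return GenotypeMatrix(tuple(t.index), mm, calls)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index=False, na_rep=NA)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    t = pd.read_csv(path, na_values=[NA], keep_default_na=False)
    for col in ("fat_mg", "lean_mg"):
        if col not in t.columns:
            raise ValueError(f"{path}: missing column {col!r}")
        vals = pd.to_numeric(t[col], errors="coerce")
        bad = t.index[vals.isna() & t[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col} at data row(s) {list(bad + 2)[:5]}"
            )
        t[col] = vals
    try:
        validate_phenotypes(t)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e
    return t


def extra_trait_columns(pheno: pd.DataFrame) -> list[str]:
    """Numeric columns beyond the core schema, usable for genetic correlations."""
    core = {"animal_id", "strain", "sex", "diet", "fat_mg", "lean_mg"}
    return [
        c
        for c in pheno.columns
        if c not in core and pd.api.types.is_numeric_dtype(pheno[c])
    ]


# ---------------------------------------------------------------------------
# Flat key=value config files
# ---------------------------------------------------------------------------

def read_flat_config(path: str | Path) -> dict[str, str]:
    """Parse ``key = value`` lines; '#' starts a comment; keys may be dotted."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if not key:
            raise ValueError(f"{path}:{ln}: empty key")
        out[key] = val
    return out


def write_flat_config(cfg: dict, path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in cfg.items()]
    Path(path).write_text("\n".join(lines) + "\n")
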