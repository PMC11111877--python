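"""Readers and writers for the plain-text interchange formats.

All pipeline stages communicate through these formats: one-gene-per-line
universe files, GMT gene-set databases (with an extension for signed regulon
modes), genes x samples TSV matrices, and survival/clinical TSV tables.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .datatypes import GeneUniverse, OmicsGeneSet


# ---------------------------------------------------------------------------
# universe

def read_universe(path: str | Path) -> GeneUniverse:
    genes = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return GeneUniverse(tuple(genes))


def write_universe(universe: GeneUniverse, path: str | Path) -> None:
    Path(path).write_text("\n".join(universe.genes) + "\n")


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need >= 3 fields): {line[:80]!r}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name in GMT: {name!r}")
        sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_regulon_gmt(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a GMT whose members carry mode suffixes, e.g. ``GENE:+1`` / ``GENE:-1``.

    Members without a suffix default to mode +1.
    """
    out: dict[str, dict[str, float]] = {}
    for name, members in read_gmt(path).items():
        modes: dict[str, float] = {}
        for token in members:
            gene, sep, mode = token.rpartition(":")
            if sep:
                modes[gene] = float(mode)
            else:
                modes[token] = 1.0
        out[name] = modes
    return out


def write_regulon_gmt(regulons: dict[str, dict[str, float]], path: str | Path) -> None:
    sets = {
        tf: [f"{g}:{'+1' if m > 0 else '-1'}" for g, m in modes.items()]
        for tf, modes in regulons.items()
    }
    write_gmt(sets, path)


# ---------------------------------------------------------------------------
# matrices and tables

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_query_set(path: str | Path, name: str | None = None) -> OmicsGeneSet:
    """Read a query gene set from a two-column TSV (gene, logFC) or a gene list."""
    path = Path(path)
    genes: list[str] = []
    logfc: dict[str, float] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "gene":  # header
            continue
        genes.append(parts[0])
        if len(parts) > 1:
            logfc[parts[0]] = float(parts[1])
    return OmicsGeneSet(name or path.stem, genes, logfc)


def read_survival(path: str | Path) -> pd.DataFrame:
    """Survival/clinical TSV with at least columns sample, time, event."""
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    return df.set_index("sample")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
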