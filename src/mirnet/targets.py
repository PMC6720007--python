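"""Consensus integration of predicted miRNA->target tables.

Prediction databases disagree heavily; the pipeline keeps only interactions
supported by at least ``min_sources`` independent sources, restricted to the
differentially expressed miRNAs and the disease-associated gene universe.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import InputError

__all__ = [
    "normalize_mirna_id",
    "read_target_table",
    "read_universe",
    "consensus_edges",
    "targets_of",
]


def normalize_mirna_id(mirna_id: str, mode: str = "strip_species") -> str:
    """Lowercase and optionally strip the species prefix (hsa-/mmu-)."""
    s = str(mirna_id).strip().lower()
    if mode == "strip_species":
        for prefix in ("hsa-", "mmu-"):
            if s.startswith(prefix):
                s = s[len(prefix):]
                break
    elif mode != "none":
        raise InputError(f"unknown id normalization mode {mode!r}")
    return s


def read_target_table(path: str | Path) -> pd.DataFrame:
    """Read a per-source TSV of (mirna_id, gene_id[, score]); score ignored."""
    table = pd.read_csv(path, sep="\t")
    for col in ("mirna_id", "gene_id"):
        if col not in table.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return table[["mirna_id", "gene_id"]]


def read_universe(path: str | Path,
                  alias_map: str | Path | None = None) -> set[str]:
    """Gene universe: one symbol per line; optional two-column alias map TSV."""
    genes = {line.strip() for line in Path(path).read_text().splitlines()
             if line.strip()}
    if alias_map is not None:
        aliases = pd.read_csv(alias_map, sep="\t", header=None,
                              names=["alias", "symbol"])
        mapping = dict(zip(aliases["alias"], aliases["symbol"]))
        genes = {mapping.get(g, g) for g in genes}
    if not genes:
        raise InputError("gene universe is empty")
    return genes


def consensus_edges(tables: list[pd.DataFrame],
                    universe: set[str],
                    mirnas: set[str],
                    min_sources: int = 2,
                    id_normalization: str = "strip_species",
                    source_names: list[str] | None = None) -> pd.DataFrame:
    """Edges supported by >= ``min_sources`` distinct prediction sources.

    An edge is emitted iff it appears in at least ``min_sources`` tables
    (duplicates within one source counted once), its miRNA belongs to the
    supplied (DE) set and its gene to the universe.

    Returns a DataFrame (mirna_id, gene_id, support_count, sources) sorted by
    (mirna_id, gene_id); miRNA ids in the output are normalized.
    """
    if len(tables) < min_sources:
        raise InputError(
            f"need >= {min_sources} source tables, got {len(tables)}")
    if not universe:
        raise InputError("gene universe is empty")
    if not mirnas:
        raise InputError("miRNA set is empty")
    norm_mirnas = {normalize_mirna_id(m, id_normalization) for m in mirnas}
    names = source_names or [f"source{k}" for k in range(len(tables))]
    support: dict[tuple[str, str], set[str]] = {}
    for name, table in zip(names, tables):
        seen = set()
        for mid, gid in zip(table["mirna_id"], table["gene_id"]):
            edge = (normalize_mirna_id(mid, id_normalization), str(gid))
            if edge in seen:
                continue
            seen.add(edge)
            if edge[0] in norm_mirnas and edge[1] in universe:
                support.setdefault(edge, set()).add(name)
    rows = [(m, g, len(srcs), ",".join(sorted(srcs)))
            for (m, g), srcs in support.items() if len(srcs) >= min_sources]
    out = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "support_count",
                                      "sources"])
    return out.sort_values(["mirna_id", "gene_id"]).reset_index(drop=True)


def targets_of(edges: pd.DataFrame, mirna_id: str,
               id_normalization: str = "strip_species") -> set[str]:
    """All genes with a consensus edge from ``mirna_id`` (empty set if none)."""
    mid = normalize_mirna_id(mirna_id, id_normalization)
    return set(edges.loc[edges["mirna_id"] == mid, "gene_id"])
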