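"""Over-representation analysis of gene sets against a GMT collection.

Hypergeometric upper-tail testing of a query gene set (a network module's
genes, or one miRNA's consensus targets) against each named set, with BH
adjustment across terms and a greedy Jaccard filter for reporting a
non-redundant top list.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = ["read_gmt", "enrich", "top_nonredundant"]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Standard GMT: one set per line — name, description, then members."""
    collection: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(f"{path}:{lineno}: GMT line has < 3 fields")
        collection[fields[0]] = [g for g in fields[2:] if g]
    return collection


def enrich(query: set[str],
           collection: dict[str, list[str]],
           universe: set[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each named set.

    Query genes outside the universe are dropped with a warning; set members
    outside the universe are ignored. p is the upper-tail probability of the
    observed overlap or more; q is BH across all terms tested.

    Returns a DataFrame sorted by ascending p with columns: term, overlap,
    set_size, query_size, universe_size, p_value, q_value, overlap_genes.
    """
    if not universe:
        raise InputError("universe is empty")
    stray = set(query) - universe
    if stray:
        warnings.warn(f"{len(stray)} query genes outside universe dropped")
    query = set(query) & universe
    if not query:
        raise InputError("query is empty after universe filtering")
    N, n = len(universe), len(query)
    rows = []
    for term, members in collection.items():
        in_universe = set(members) & universe
        overlap = sorted(in_universe & query)
        k, K = len(overlap), len(in_universe)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, p, ",".join(overlap)))
    result = pd.DataFrame(rows, columns=["term", "overlap", "set_size",
                                         "query_size", "universe_size",
                                         "p_value", "overlap_genes"])
    from .expression import benjamini_hochberg
    result["q_value"] = benjamini_hochberg(result["p_value"].values)
    result = result.sort_values(["p_value", "term"]).reset_index(drop=True)
    return result[["term", "overlap", "set_size", "query_size",
                   "universe_size", "p_value", "q_value", "overlap_genes"]]


def _jaccard(a: set[str], b: set[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def top_nonredundant(result: pd.DataFrame, n: int = 5,
                     max_jaccard: float = 0.5) -> pd.DataFrame:
    """Greedy non-redundant top terms by ascending p.

    Walks terms in order of increasing p (ties by term name) and skips any
    whose overlapping-gene Jaccard similarity with an already-selected term
    exceeds ``max_jaccard``; stops after ``n`` selections.
    """
    if result.empty:
        raise InputError("enrichment result is empty")
    ordered = result.sort_values(["p_value", "term"])
    selected: list[int] = []
    selected_genes: list[set[str]] = []
    for idx, row in ordered.iterrows():
        genes = set(str(row["overlap_genes"]).split(",")) - {""}
        if any(_jaccard(genes, s) > max_jaccard for s in selected_genes):
            continue
        selected.append(idx)
        selected_genes.append(genes)
        if len(selected) == n:
            break
    return result.loc[selected].reset_index(drop=True)
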