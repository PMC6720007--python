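"""Heterogeneous miRNA-gene regulatory network: construction, modules, traffic.

The combined graph joins consensus miRNA->target edges to a protein-protein
interaction layer over the disease gene universe. It is treated as undirected
and unweighted: the "traffic score" of a node is its shortest-path
betweenness centrality, modules are communities found by modularity
optimization, and candidate miRNAs are ranked within a module by traffic
score then differential-expression q-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import InputError
from .targets import normalize_mirna_id

__all__ = [
    "build_network",
    "traffic_scores",
    "detect_modules",
    "rank_candidates",
    "ModulePartition",
]


def build_network(consensus: pd.DataFrame,
                  ppi: pd.DataFrame,
                  universe: set[str] | None = None) -> nx.Graph:
    """Combine consensus miRNA-gene edges with gene-gene PPI edges.

    Nodes carry ``kind`` ('mirna' or 'gene'), edges carry ``kind``
    ('mirna_gene' or 'ppi'). PPI edges touching a gene outside the universe
    (when given) are dropped; a PPI edge naming a miRNA id is an input error;
    self-loops and duplicate edges are collapsed.
    """
    if consensus.empty or ppi.empty:
        raise InputError("consensus and ppi inputs must be non-empty")
    g = nx.Graph()
    for mid, gid in zip(consensus["mirna_id"], consensus["gene_id"]):
        g.add_node(mid, kind="mirna")
        g.add_node(gid, kind="gene")
        g.add_edge(mid, gid, kind="mirna_gene")
    mirna_ids = {n for n, k in g.nodes(data="kind") if k == "mirna"}
    for a, b in zip(ppi.iloc[:, 0], ppi.iloc[:, 1]):
        a, b = str(a), str(b)
        if a in mirna_ids or b in mirna_ids:
            raise InputError(f"PPI edge ({a}, {b}) names a miRNA id")
        if a == b:
            continue
        if universe is not None and (a not in universe or b not in universe):
            continue
        g.add_node(a, kind="gene")
        g.add_node(b, kind="gene")
        if not g.has_edge(a, b):
            g.add_edge(a, b, kind="ppi")
    return g


def traffic_scores(net: nx.Graph, normalized: bool = False) -> pd.Series:
    """Exact shortest-path betweenness centrality ("traffic score").

    Endpoints are excluded and contributions split evenly across equal-length
    shortest paths (Brandes accumulation); optional normalization by
    (n-1)(n-2)/2.
    """
    if net.number_of_nodes() == 0:
        raise InputError("network is empty")
    scores = nx.betweenness_centrality(net, normalized=normalized)
    return pd.Series(scores, name="traffic_score").sort_index()


@dataclass
class ModulePartition:
    """Node -> module id (1..M) with the partition's modularity."""

    module_of: dict[str, int]
    modularity: float

    def members(self, module_id: int) -> set[str]:
        return {n for n, m in self.module_of.items() if m == module_id}

    @property
    def n_modules(self) -> int:
        return len(set(self.module_of.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.module_of.items()),
            columns=["node_id", "module_id"])


def detect_modules(net: nx.Graph, resolution: float = 1.0,
                   seed: int = 0) -> ModulePartition:
    """Modularity-maximizing partition (Louvain-style multilevel refinement).

    Deterministic for a fixed seed; disconnected components are handled
    naturally by the modularity objective. Modules are renumbered 1..M by
    decreasing size (ties by smallest member id) so labels are stable.
    """
    if net.number_of_nodes() == 0:
        raise InputError("network is empty")
    communities = nx.community.louvain_communities(
        net, resolution=resolution, seed=int(seed))
    modularity = nx.community.modularity(net, communities,
                                         resolution=resolution)
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    module_of = {n: i + 1 for i, c in enumerate(ordered) for n in c}
    return ModulePartition(module_of=module_of, modularity=float(modularity))


def rank_candidates(partition: ModulePartition,
                    traffic: pd.Series,
                    de: pd.DataFrame,
                    module_id: int,
                    k: int = 10) -> pd.DataFrame:
    """Rank a module's miRNAs: top-k by traffic score, reordered by q-value.

    The k miRNAs of the module with the highest traffic scores are selected
    (ties broken by ascending q then lexicographic id) and then ordered by
    ascending differential-expression q-value; rank 1 is the nominated
    candidate.
    """
    q_of = {normalize_mirna_id(m): q for m, q in de["q_value"].items()}
    members = [n for n in partition.members(module_id) if n in q_of]
    if not members:
        warnings.warn(f"module {module_id} contains no miRNA with a DE record")
        return pd.DataFrame(columns=["mirna_id", "module_id", "traffic_score",
                                     "q_value", "rank"])
    rows = pd.DataFrame({
        "mirna_id": members,
        "module_id": module_id,
        "traffic_score": [float(traffic.get(n, 0.0)) for n in members],
        "q_value": [q_of[n] for n in members],
    })
    top = rows.sort_values(["traffic_score", "q_value", "mirna_id"],
                           ascending=[False, True, True]).head(k)
    out = top.sort_values(["q_value", "mirna_id"]).reset_index(drop=True)
    out["rank"] = out.index + 1
    return out


# ---- I/O ----

def write_network(net: nx.Graph, edges_path: str | Path,
                  nodes_path: str | Path) -> None:
    pd.DataFrame(
        [(a, b, d["kind"]) for a, b, d in net.edges(data=True)],
        columns=["node_a", "node_b", "edge_kind"],
    ).to_csv(edges_path, sep="\t", index=False)
    pd.DataFrame(
        sorted((n, d["kind"]) for n, d in net.nodes(data=True)),
        columns=["node_id", "node_kind"],
    ).to_csv(nodes_path, sep="\t", index=False)


def read_network(edges_path: str | Path, nodes_path: str | Path) -> nx.Graph:
    nodes = pd.read_csv(nodes_path, sep="\t")
    edges = pd.read_csv(edges_path, sep="\t")
    g = nx.Graph()
    for nid, kind in zip(nodes["node_id"], nodes["node_kind"]):
        g.add_node(str(nid), kind=kind)
    for a, b, kind in zip(edges["node_a"], edges["node_b"],
                          edges["edge_kind"]):
        g.add_edge(str(a), str(b), kind=kind)
    return g
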