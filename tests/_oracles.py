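"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the implementation paths they check: betweenness by
exhaustive enumeration of all shortest paths, AUC via the rank-sum identity,
consensus by hash counting.
"""

from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Betweenness by explicit enumeration of every shortest path.

    For each unordered node pair, all shortest paths are listed via
    ``nx.all_shortest_paths`` (path enumeration, not Brandes accumulation);
    each internal node of each path receives 1/(number of shortest paths for
    that pair). Endpoints excluded; feasible only for tiny graphs.
    """
    scores = {n: 0.0 for n in graph}
    for s, t in combinations(graph.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for node in path[1:-1]:
                scores[node] += 1.0 / len(paths)
    return scores


def rank_sum_auc(case_levels, control_levels) -> float:
    """AUC as the tie-corrected Mann-Whitney U divided by n1*n2.

    Computed from mid-ranks directly, independent of any ROC sweep.
    """
    case_levels = np.asarray(case_levels, dtype=float)
    control_levels = np.asarray(control_levels, dtype=float)
    n1, n0 = len(case_levels), len(control_levels)
    ranks = stats.rankdata(np.concatenate([case_levels, control_levels]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return u / (n1 * n0)


def brute_force_consensus(tables, universe, mirnas, min_sources):
    """Consensus edges by hash-counting deduplicated per-source edge sets."""
    counts = {}
    for table in tables:
        for edge in {(m, g) for m, g in
                     zip(table["mirna_id"], table["gene_id"])}:
            counts[edge] = counts.get(edge, 0) + 1
    return {e for e, c in counts.items()
            if c >= min_sources and e[0] in mirnas and e[1] in universe}
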