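"""Enrichment-guided module selection and candidate miRNA nomination.

Selects the module most enriched for the vessel-biology gene set, takes its
ten highest-traffic miRNAs, reorders them by differential-expression
q-value, nominates the rank-1 miRNA, and characterises the processes
enriched by the candidate's consensus targets.
"""

import json
from pathlib import Path

import pandas as pd

from mirnet import enrichment as enr
from mirnet import expression as expr
from mirnet import network as net
from mirnet import targets as tgt
from mirnet.targets import normalize_mirna_id

ROOT = Path(__file__).resolve().parent.parent / "results"
BUNDLE = ROOT / "synthetic_bundle"
ANCHOR = "vasculature_development"


def main() -> None:
    enrichment = pd.read_csv(ROOT / "module_enrichment.tsv", sep="\t")
    anchor_rows = enrichment[enrichment["term"] == ANCHOR]
    module_id = int(anchor_rows.sort_values("p_value").iloc[0]["module_id"])
    print(f"module {module_id} is most enriched for {ANCHOR}")

    part_df = pd.read_csv(ROOT / "modules.tsv", sep="\t")
    partition = net.ModulePartition(
        dict(zip(part_df["node_id"], part_df["module_id"])), float("nan"))
    traffic = pd.read_csv(ROOT / "traffic_scores.tsv", sep="\t",
                          index_col="node_id")["traffic_score"]
    de = expr.read_de_table(ROOT / "de_table.tsv")
    ranking = net.rank_candidates(partition, traffic, de, module_id, k=10)
    ranking.to_csv(ROOT / "candidate_ranking.tsv", sep="\t", index=False)
    print(ranking.head(10).to_string(index=False))

    nominated = ranking.iloc[0]["mirna_id"]
    truth = json.loads((BUNDLE / "ground_truth.json").read_text())
    planted = normalize_mirna_id(truth["candidate_mirna"])
    print(f"nominated candidate: {nominated} "
          f"(planted: {planted}; match: {nominated == planted})")

    consensus = pd.read_csv(ROOT / "consensus_edges.tsv", sep="\t")
    targets = tgt.targets_of(consensus, nominated)
    universe = tgt.read_universe(BUNDLE / "universe.txt")
    result = enr.enrich(targets, enr.read_gmt(BUNDLE / "genesets.gmt"),
                        universe)
    top5 = enr.top_nonredundant(result, n=5, max_jaccard=0.5)
    top5.to_csv(ROOT / "candidate_target_enrichment.tsv", sep="\t",
                index=False)
    print(f"{len(targets)} consensus targets; top processes:")
    print(top5[["term", "overlap", "p_value"]].to_string(index=False))


if __name__ == "__main__":
    main()
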