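"""Consensus miRNA->target integration under the >=2-source rule.

Intersects the three per-source prediction tables, keeping only interactions
reported by at least two sources whose miRNA passed the differential-
expression cutoffs and whose gene belongs to the disease universe.
"""

from pathlib import Path

from mirnet import expression as expr
from mirnet import targets as tgt

ROOT = Path(__file__).resolve().parent.parent / "results"
BUNDLE = ROOT / "synthetic_bundle"


def main() -> None:
    de = expr.read_de_table(ROOT / "de_table.tsv")
    de_mirnas = set(de.index[de["passes_cutoffs"]])
    universe = tgt.read_universe(BUNDLE / "universe.txt")
    tables = [tgt.read_target_table(p)
              for p in sorted(BUNDLE.glob("targets_source*.tsv"))]
    edges = tgt.consensus_edges(tables, universe, de_mirnas, min_sources=2)
    edges.to_csv(ROOT / "consensus_edges.tsv", sep="\t", index=False)
    print(f"{len(edges)} interactions predicted by >=2 of {len(tables)} "
          f"sources, covering {edges['mirna_id'].nunique()} DE miRNAs "
          f"and {edges['gene_id'].nunique()} genes")
    full = edges[edges["support_count"] == len(tables)]
    print(f"{len(full)} supported by all sources -> "
          f"{ROOT / 'consensus_edges.tsv'}")


if __name__ == "__main__":
    main()
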