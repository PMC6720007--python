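# mirnet

Network-based prioritization of candidate microRNAs and evaluation of their
circulating-biomarker potential, modelled on the discovery design used in
thoracic aortic aneurysm (TAA) studies: a tissue cohort profiled on miRNA
microarrays nominates a candidate through a miRNA–gene interaction network,
and an independent serum cohort evaluates that candidate as a diagnostic
marker.

The package is organised as an analysis project: the library under
`src/mirnet/` implements every stage, the numbered scripts under `analysis/`
run the study narrative end-to-end on synthetic cohorts with known ground
truth, and `scripts/acceptance.py` recomputes the headline quantities from
scratch.

## The pipeline

1. **Expression** (`mirnet.expression`) — a probes × samples log2 matrix is
   filtered for detection (signal above the per-sample 0.9-quantile of
   negative-control probes in ≥ half the samples), then each miRNA is tested
   case vs control (Welch's *t* on log2 signal, Benjamini–Hochberg FDR).
   A miRNA is differentially expressed (DE) when *q* < 0.05,
   |log2FC| > 0.5 and mean log2 expression > 5.
2. **Consensus targets** (`mirnet.targets`) — predicted miRNA→gene
   interactions from several sources are kept only when reported by ≥ 2
   sources, restricted to the DE miRNAs and a disease-associated gene
   universe.
3. **Network** (`mirnet.network`) — consensus miRNA–gene edges are combined
   with protein–protein interactions into one undirected graph. Each node's
   *traffic score* is its shortest-path betweenness centrality
   ∑_{s≠v≠t} σ_st(v)/σ_st; modules are communities found by modularity
   optimization (Louvain).
4. **Enrichment & ranking** (`mirnet.enrichment`, `mirnet.network`) — each
   module's genes are tested for over-representation against a GMT
   collection (hypergeometric upper tail, BH across terms, greedy Jaccard
   filter for a non-redundant top-5). Within the module of interest, the
   ten highest-traffic miRNAs are reordered by DE *q*-value; rank 1 is the
   nominated candidate.
5. **Biomarker** (`mirnet.biomarker`) — serum levels are compared between
   groups (Shapiro–Wilk-gated *t*/Mann–Whitney, median fold change) and
   evaluated by ROC: AUC by trapezoid (= tie-corrected U/(n₁n₂)), reporting
   cutoff by the Youden index J = sensitivity + specificity − 1; cases are
   split at the median aneurysm diameter, and levels are correlated with
   diameter by Spearman's ρ.

The synthetic-data module (`mirnet.synthdata`) generates every input with
planted ground truth — DE miRNAs, gene communities, true target edges, and a
serum effect size δ = Φ⁻¹(AUC)·√2·σ calibrated so the expected AUC is 0.87
with a ~3-fold median shift — so each stage's recovery can be verified.

## Worked example

Running the analysis scripts in order (about 15 s total):

```
python analysis/01_simulate_cohorts.py
python analysis/02_differential_expression.py
python analysis/03_consensus_targets.py
python analysis/04_network_modules.py
python analysis/05_candidate_ranking.py
python analysis/06_serum_biomarker.py
```

prints, for the default seed-42 bundle:

```
473 of 500 miRNAs detected
52 differentially expressed miRNAs (30 up, 22 down) -> results/de_table.tsv
...
343 interactions predicted by >=2 of 3 sources, covering 50 DE miRNAs and 111 genes
network: 170 nodes, 937 edges (343 miRNA-gene + PPI)
4 modules (modularity 0.649)
module 3 is most enriched for vasculature_development
nominated candidate: mir-0104 (planted: mir-0104; match: True)
28 cases vs 20 controls: 2.56-fold (mannwhitney, p=4.60e-03)
AUC 0.743; ... sensitivity 64.3%, specificity 85.0%
Spearman level vs diameter: rho=0.920, p=4.37e-12
```

Reading: of 500 simulated miRNAs, 473 pass detection and 52 pass the DE
cutoffs (50 planted plus 2 false calls); consensus filtering and network
module decomposition isolate the vessel-biology module, whose
highest-traffic, most-DE miRNA is exactly the planted candidate; in the
serum cohort the candidate separates 28 cases from 20 controls. The single
28/20 draw shown has AUC 0.74 — at that cohort size the empirical AUC
scatters around its calibrated expectation of 0.87 (the acceptance script
reports the mean over many cohorts). All tables land in `results/`.

The same stages are available as a CLI (`mirnet simulate|de|consensus|
network|enrich|biomarker|run`); `mirnet run --config cfg.yaml` executes the
whole pipeline from one YAML file and writes a manifest with per-stage
counts and checksums.

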