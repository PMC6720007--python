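# Methods

This note documents the models, parameter choices and numerical conventions
behind `mirnet`, and what the synthetic cohorts do and do not establish
about behaviour on real data.

## Study design being emulated

The pipeline mirrors a two-cohort discovery/validation design for thoracic
aortic aneurysm (TAA): a *tissue cohort* (aortic-media miRNA microarrays,
19 cases vs 19 controls) drives candidate discovery through a miRNA–gene
interaction network over a disease-associated gene universe, and a separate
*serum cohort* (28 cases vs 20 controls) evaluates the candidate's
circulating levels as a diagnostic marker. All external resources that such
a study queries online — target-prediction databases, a PPI database, a
gene-set annotation service — are file inputs here; the package integrates
them but does not re-implement target prediction or re-execute literature
searches.

## Expression stage

Signals are modelled and analysed on the log2 scale throughout.

- **Detection filter.** A miRNA is detected in a sample when its signal
  exceeds the `negctrl_quantile` (default 0.9) quantile of that sample's
  negative-control probe signals, and retained when detected in at least
  `min_sample_frac` (default 0.5) of samples. The 0.9 quantile is a
  conservative operationalization of "above the negative controls"; both
  knobs are exposed.
- **Differential expression.** Welch's unequal-variance *t*-test per miRNA
  by default (a tie-corrected normal-approximation Mann–Whitney is
  available), BH step-up adjustment across all tested miRNAs, and three
  simultaneous cutoffs: *q* < 0.05, |log2FC| > 0.5, mean log2 expression
  > 5. The expression cutoff is interpreted on the mean log2 normalized
  signal and exposed (`expr_min`), since "relative expression" thresholds
  are convention-dependent. Rows with zero variance in both groups receive
  p = 1 rather than NaN. Moderated-variance (empirical-Bayes) testing is
  deliberately not used; the plain two-sample test keeps the stage
  assumption-light and matches the normality-gated t/Mann–Whitney
  convention used for the clinical variables.
- **Probe collapse.** Arrays carry multiple probes per miRNA; when a
  probe→miRNA map is supplied, probes are collapsed by the per-sample
  median before testing.
- **PCA** is computed on mean-centered samples-in-miRNA-space via full SVD;
  scores are deterministic up to component sign.

## Consensus targets

miRNA identifiers are lowercased and stripped of species prefixes
(`hsa-`/`mmu-`) before matching (`strip_species`; `none` available),
because prediction sources disagree on prefix conventions. Within one
source duplicate edges count once; an edge needs `min_sources` (default 2)
distinct sources, a miRNA in the supplied DE set and a gene in the
universe. Per-source prediction scores are ignored — no evidence threshold
is applied before the consensus vote.

## Network stage

The combined graph is **undirected and unweighted**: edge kinds
(`mirna_gene`, `ppi`) are kept as annotations for filtering but ignored by
centrality, since the traffic score is defined as plain shortest-path
betweenness. Traffic scores use exact Brandes betweenness with endpoints
excluded and equal splitting across tied shortest paths; normalization by
(n−1)(n−2)/2 is optional and off by default, so leaf nodes score exactly 0.
Traffic is computed on the full network by default (computing it per module
is possible by subsetting the graph); module detection is Louvain
modularity maximization with a fixed seed and a resolution parameter to
steer module granularity. Modules are renumbered 1..M by decreasing size
with ties broken by smallest member id, so labels are stable across reruns.

Candidate ranking takes the k = 10 highest-traffic miRNAs of one module
(ties by ascending *q*, then id) and reorders them by ascending DE
*q*-value. Module *selection* is a judgment call in the original design
(made by inspecting enriched processes), so the pipeline surfaces it as
either an explicit `module_id` or the module most enriched for a named
gene set (`target_geneset`) — it is not inferred silently.

## Enrichment

One-sided hypergeometric upper-tail tests (equivalent to Fisher's exact,
greater) against each GMT set, restricted to a declared universe — by
default the disease gene universe, not the genome, because the queries are
themselves subsets of that universe. BH adjustment across terms. The
"non-redundant top five" is operationalized greedily: walk terms by
ascending p and skip any whose overlapping-gene Jaccard similarity with an
already-selected term exceeds `max_jaccard` (default 0.5).

## Biomarker stage

- **Group comparison.** Shapiro–Wilk on each group gates the test choice at
  α = 0.05: both normal → Welch's *t*; otherwise Mann–Whitney with tie
  correction. For groups above 5000 the gate defaults to the nonparametric
  branch. Fold change is the ratio of group medians (mean ratio optional).
- **ROC.** Case is the positive class; a level above the threshold is
  test-positive. Thresholds sweep the observed values; AUC is the
  trapezoidal area, which equals the tie-corrected Mann–Whitney
  U/(n₁n₂) identically (this identity is enforced to 1e−12 in the tests).
  The reporting cutoff maximizes the Youden index, with ties broken toward
  higher specificity.
- **Subgrouping and correlation.** Cases are split at the case-median of a
  covariate (the median subject goes to the low group); correlations are
  Spearman with mid-ranks and the *t*-approximation for p.

## Synthetic cohorts: what they emulate

`SimulationConfig` defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_cases`, `n_controls` | 19, 19 | tissue cohort size |
| `n_mirnas`, `n_negctrl_probes` | 500, 50 | array content |
| `frac_de`, `de_log2fc_magnitude` | 0.1, 1.0 | planted DE fraction and effect (log2) |
| `within_group_sd` | 0.5 | log2 residual SD |
| `baseline_mean`, `baseline_sd` | 7.0, 0.75 | per-miRNA baseline distribution (log2) |
| `detection_dropout_rate` | 0.05 | fraction of low-expressed miRNAs |
| `candidate_boost` | 3.0 | effect multiplier for the designated candidate |
| `n_genes`, `n_communities` | 120, 4 | disease gene universe with planted communities |
| `p_within`, `p_between` | 0.3, 0.01 | planted-partition PPI edge probabilities |
| `n_sources`, `source_agreement` | 3, 0.8 | prediction sources and per-source recall |
| `edges_per_mirna` | 8 | true targets per DE miRNA (3× for the candidate) |
| `target_auc`, `serum_sd_log` | 0.87, 0.69 | serum calibration (log-normal) |
| `n_serum_cases`, `n_serum_controls` | 28, 20 | serum cohort size |

Design choices within the generator:

- **Expression noise** is Gaussian on the log2 scale with a common
  within-group SD — an assumption, not a reconstruction of any array error
  model; no probe-level chemistry, dye effects or batch structure are
  simulated.
- **Detection dropout** is row-structured: a `detection_dropout_rate`
  fraction of miRNAs is low-expressed, with all entries drawn below the
  negative-control level, so the detection filter has a recoverable ground
  truth. Per-entry dropout sprinkled uniformly into expressed rows was
  rejected as unrealistic — on arrays, non-detection concentrates in weakly
  expressed probes — and because isolated −4 log2 outliers would dominate
  the per-row variance in a way no plausible normalization would leave in
  place. DE effects are planted among expressed miRNAs only, since an
  effect in an undetectable miRNA is unobservable by construction.
- **The designated candidate** anchors end-to-end recovery: one planted
  miRNA receives `candidate_boost` × the common effect magnitude and three
  times the usual out-degree, concentrated (85%, like all miRNAs' home
  bias) in community 0, whose gene set is named `vasculature_development`.
  The boost of 3 makes the candidate's "strongest DE in its module" label
  hold with margin at n = 19 + 19 — at smaller boosts the per-row variance
  noise of the *t*-statistic can reorder extreme q-values between planted
  miRNAs, which would make "the planted candidate" an ill-defined target
  for a recovery test rather than a property of the generative structure.
- **Negative controls** are Normal(baseline_mean − 3, within_group_sd):
  the only constraint the design imposes is that true signal must exceed
  them.
- **Serum levels** are log-normal with equal log-scale group SDs σ, so the
  binormal identity AUC = Φ(δ/√(2σ²)) gives the calibrated shift
  δ = Φ⁻¹(AUC)·√2·σ in closed form. With σ = 0.69, calibrating to
  AUC 0.87 gives δ ≈ ln 3, i.e. a ~3-fold median shift — the default
  reproduces both headline properties of the serum arm jointly. The
  aneurysm-diameter covariate of cases is a linear function of the
  standardized log level (slope 5 mm per log-SD around 49 mm, noise
  SD 2 mm, floor 30 mm), giving a known positive rank correlation.
- **Prediction sources** report each true edge independently with
  probability `source_agreement` and add 50% decoy edges each;
  **gene sets** are the planted communities plus random decoy sets of the
  median community size.

Passing tests on these cohorts establish that the pipeline's statistics are
exact (graph centrality, consensus counting, AUC identity, hypergeometric
tails), that its error control and recovery behave as designed under the
assumed Gaussian/log-normal models, and that the stages compose correctly.
They do not establish robustness to array normalization artifacts,
correlated probe noise, annotation errors in real prediction databases, or
case-mix heterogeneity in clinical cohorts.

## Problem sizes and determinism

The shipped analyses and checks use 500 miRNAs × 38 samples, a 120-gene
4-community universe, 3 prediction sources, and serum cohorts of 28/20
(2000/2000 for large-sample calibration); replicated checks use 20–500
replicates per property and the end-to-end nomination check uses 50 seeded
bundles. These sizes were chosen so every property is measured with
comfortable Monte-Carlo margin while the whole suite runs in well under a
minute of compute. Every generator draws from `numpy.random.default_rng`
seeded per-stream from the config seed, so all outputs — including written
bundles and pipeline manifests — are byte-identical across reruns with the
same seed.

## Known limitations

- The detection filter and DE test assume one row per miRNA after optional
  probe collapse; no within-array spatial or background correction is
  provided.
- Betweenness is exact, not sampled; networks far larger than the study
  scale (~10³ nodes) would need approximate centrality.
- The enrichment model ignores term ancestry (no GO-graph propagation) and
  treats sets as flat gene lists.
- ROC confidence intervals (e.g. DeLong) and covariate-adjusted AUC are out
  of scope; reported sensitivities/specificities at the Youden cutoff are
  point estimates and optimistically biased at small n.
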