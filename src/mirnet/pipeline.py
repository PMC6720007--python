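"""End-to-end orchestration: expression -> consensus -> network -> ranking -> biomarker.

The pipeline reproduces the discovery axis of the study design on any input
bundle (typically one produced by :mod:`mirnet.synthdata`): filter and test
the expression matrix, integrate predicted targets under the >=2-source rule,
build the combined miRNA-gene/PPI network, decompose it into modules, score
traffic (betweenness), pick the working module by gene-set enrichment (or an
explicit module id), rank the module's miRNAs, and evaluate the circulating
biomarker with group comparison + ROC. Every intermediate is written next to
a JSON run manifest with per-stage counts and file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import biomarker as bm
from . import enrichment as enr
from . import expression as expr
from . import network as net
from . import targets as tgt
from .errors import ConfigError, InputError, StageError

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("mirnet")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one reproducible pipeline run."""

    matrix: str
    samples: str
    sources: list[str]
    universe: str
    ppi: str
    gmt: str
    serum: str | None = None
    outdir: str = "results"
    # thresholds
    q_max: float = 0.05
    fc_min: float = 0.5
    expr_min: float = 5.0
    min_sample_frac: float = 0.5
    negctrl_quantile: float = 0.9
    min_sources: int = 2
    resolution: float = 1.0
    top_k: int = 10
    max_jaccard: float = 0.5
    # module selection: explicit id, or the module most enriched for a set
    module_id: int | None = None
    target_geneset: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("matrix", "samples", "universe", "ppi", "gmt"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name}: path does not exist: {p}")
        for p in self.sources:
            if not Path(p).exists():
                raise ConfigError(f"sources: path does not exist: {p}")
        if self.serum is not None and not Path(self.serum).exists():
            raise ConfigError(f"serum: path does not exist: {self.serum}")
        for name, lo, hi in (("q_max", 0, 1), ("fc_min", 0, float("inf")),
                             ("min_sample_frac", 0, 1),
                             ("negctrl_quantile", 0, 1),
                             ("max_jaccard", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ConfigError(f"{name} out of range: {v}")
        if self.min_sources < 1:
            raise ConfigError("min_sources must be >= 1")
        if self.module_id is None and self.target_geneset is None:
            raise ConfigError(
                "set module_id or target_geneset to select the working module")

    @classmethod
    def for_bundle(cls, bundle_dir: str | Path, outdir: str | Path,
                   **overrides) -> "PipelineConfig":
        """Config pointing at a ``synthdata.simulate_bundle`` directory."""
        b = Path(bundle_dir)
        sources = sorted(str(p) for p in b.glob("targets_source*.tsv"))
        defaults = dict(
            matrix=str(b / "expression.tsv"), samples=str(b / "samples.tsv"),
            sources=sources, universe=str(b / "universe.txt"),
            ppi=str(b / "ppi.tsv"), gmt=str(b / "genesets.gmt"),
            serum=str(b / "serum.csv"), outdir=str(outdir),
            target_geneset="vasculature_development")
        defaults.update(overrides)
        return cls(**defaults)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(config: PipelineConfig) -> dict:
    """Schema and cross-reference checks; returns {'errors': [], 'warnings': []}."""
    errors: list[str] = []
    warnings_: list[str] = []
    try:
        config.validate()
    except ConfigError as exc:
        return {"errors": [str(exc)], "warnings": []}
    try:
        matrix = expr.ExpressionMatrix.from_tsv(config.matrix, config.samples)
    except (InputError, Exception) as exc:  # surface parse issues with context
        errors.append(f"{config.matrix}: {exc}")
        matrix = None
    universe = tgt.read_universe(config.universe)
    import pandas as pd
    ppi = pd.read_csv(config.ppi, sep="\t")
    if ppi.shape[1] > 2:
        warnings_.append(
            f"{config.ppi}: {ppi.shape[1]} columns; extra columns ignored")
    ppi_genes = set(map(str, ppi.iloc[:, 0])) | set(map(str, ppi.iloc[:, 1]))
    stray = sorted(ppi_genes - universe)
    if stray:
        warnings_.append(
            f"{len(stray)} PPI genes absent from universe (dropped at build)")
    source_mirnas: set[str] = set()
    for path in config.sources:
        try:
            table = tgt.read_target_table(path)
            source_mirnas |= {tgt.normalize_mirna_id(m)
                              for m in table["mirna_id"]}
        except InputError as exc:
            errors.append(str(exc))
    if matrix is not None:
        matrix_mirnas = {tgt.normalize_mirna_id(m)
                         for m in matrix.values.index[
                             ~matrix.negative_control_mask.values]}
        if not matrix_mirnas & source_mirnas:
            warnings_.append("no miRNA id overlap between matrix and sources")
    try:
        enr.read_gmt(config.gmt)
    except InputError as exc:
        errors.append(str(exc))
    if config.serum is not None:
        try:
            bm.read_biomarker_table(config.serum)
        except InputError as exc:
            errors.append(str(exc))
    return {"errors": errors, "warnings": warnings_}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return (and write) the run manifest.

    Any stage failure raises :class:`StageError` naming the stage; outputs of
    completed stages are retained in ``config.outdir``.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "counts": {},
                      "outputs": {}, "checksums": {}}

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)
        manifest["checksums"][name] = _sha256(path)

    stage = "expression"
    try:
        matrix = expr.ExpressionMatrix.from_tsv(config.matrix, config.samples)
        detected = expr.detection_filter(
            matrix, config.min_sample_frac, config.negctrl_quantile)
        de = expr.differential_expression(
            detected, q_max=config.q_max, fc_min=config.fc_min,
            expr_min=config.expr_min)
        expr.write_de_table(de, outdir / "de_table.tsv")
        emit("de_table", outdir / "de_table.tsv")
        de_ids = set(de.index[de["passes_cutoffs"]])
        manifest["counts"].update(
            detected_mirnas=int(detected.values.shape[0]),
            de_mirnas=len(de_ids),
            de_up=int((de["passes_cutoffs"] & (de["direction"] == "up")).sum()),
            de_down=int((de["passes_cutoffs"]
                         & (de["direction"] == "down")).sum()))
        log.info("expression: %d detected, %d DE", detected.values.shape[0],
                 len(de_ids))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "consensus"
    try:
        universe = tgt.read_universe(config.universe)
        tables = [tgt.read_target_table(p) for p in config.sources]
        consensus = tgt.consensus_edges(tables, universe, de_ids,
                                        min_sources=config.min_sources)
        consensus.to_csv(outdir / "consensus_edges.tsv", sep="\t", index=False)
        emit("consensus_edges", outdir / "consensus_edges.tsv")
        manifest["counts"]["consensus_edges"] = len(consensus)
        log.info("consensus: %d edges", len(consensus))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "network"
    try:
        import pandas as pd
        ppi = pd.read_csv(config.ppi, sep="\t")
        graph = net.build_network(consensus, ppi, universe)
        traffic = net.traffic_scores(graph)
        partition = net.detect_modules(graph, resolution=config.resolution,
                                       seed=config.seed)
        net.write_network(graph, outdir / "network_edges.tsv",
                          outdir / "network_nodes.tsv")
        emit("network_edges", outdir / "network_edges.tsv")
        emit("network_nodes", outdir / "network_nodes.tsv")
        traffic.to_csv(outdir / "traffic_scores.tsv", sep="\t",
                       index_label="node_id")
        emit("traffic_scores", outdir / "traffic_scores.tsv")
        partition.to_frame().to_csv(outdir / "modules.tsv", sep="\t",
                                    index=False)
        emit("modules", outdir / "modules.tsv")
        sizes = {m: 0 for m in set(partition.module_of.values())}
        for m in partition.module_of.values():
            sizes[m] += 1
        manifest["counts"].update(
            network_nodes=graph.number_of_nodes(),
            network_edges=graph.number_of_edges(),
            ppi_edges=sum(1 for *_, d in graph.edges(data=True)
                          if d["kind"] == "ppi"),
            n_modules=partition.n_modules,
            module_sizes={str(k): v for k, v in sorted(sizes.items())},
            modularity=partition.modularity)
        log.info("network: %d nodes, %d modules", graph.number_of_nodes(),
                 partition.n_modules)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "enrichment"
    try:
        collection = enr.read_gmt(config.gmt)
        module_enrichment = {}
        gene_nodes = {n for n, k in graph.nodes(data="kind") if k == "gene"}
        for m in sorted(set(partition.module_of.values())):
            genes = partition.members(m) & gene_nodes
            if not genes:
                continue
            module_enrichment[m] = enr.enrich(genes, collection, universe)
        if config.module_id is not None:
            module_id = config.module_id
        else:
            best, best_p = None, float("inf")
            for m, res in module_enrichment.items():
                hit = res.loc[res["term"] == config.target_geneset, "p_value"]
                p = float(hit.iloc[0]) if len(hit) else float("inf")
                if p < best_p:
                    best, best_p = m, p
            if best is None:
                raise InputError(
                    f"target gene set {config.target_geneset!r} not found")
            module_id = best
        rows = []
        for m, res in module_enrichment.items():
            top = enr.top_nonredundant(res, n=5, max_jaccard=config.max_jaccard)
            top.insert(0, "module_id", m)
            rows.append(top)
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "module_enrichment.tsv", sep="\t", index=False)
        emit("module_enrichment", outdir / "module_enrichment.tsv")
        manifest["counts"]["selected_module"] = int(module_id)
        log.info("enrichment: selected module %d", module_id)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "ranking"
    try:
        ranking = net.rank_candidates(partition, traffic, de, module_id,
                                      k=config.top_k)
        ranking.to_csv(outdir / "candidate_ranking.tsv", sep="\t", index=False)
        emit("candidate_ranking", outdir / "candidate_ranking.tsv")
        manifest["counts"]["ranked_candidates"] = len(ranking)
        nominated = ranking.iloc[0]["mirna_id"] if len(ranking) else None
        manifest["nominated_candidate"] = nominated
        if nominated is not None:
            targets = tgt.targets_of(consensus, nominated)
            cand_enr = enr.enrich(targets, collection, universe)
            top5 = enr.top_nonredundant(cand_enr, n=5,
                                        max_jaccard=config.max_jaccard)
            top5.to_csv(outdir / "candidate_target_enrichment.tsv", sep="\t",
                        index=False)
            emit("candidate_target_enrichment",
                 outdir / "candidate_target_enrichment.tsv")
            manifest["counts"]["candidate_targets"] = len(targets)
        log.info("ranking: nominated %s", nominated)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    if config.serum is not None:
        stage = "biomarker"
        try:
            serum = bm.read_biomarker_table(config.serum)
            comparison = bm.compare_groups(serum)
            roc_result = bm.roc(serum)
            roc_result.to_frame().to_csv(outdir / "roc_points.tsv", sep="\t",
                                         index=False)
            emit("roc_points", outdir / "roc_points.tsv")
            manifest["biomarker"] = {
                "comparison": comparison, **roc_result.summary()}
            if "diameter_mm" in serum.columns and \
                    serum.loc[serum["group"] == "case",
                              "diameter_mm"].notna().all():
                low, high, cut = bm.subgroup_by_median(serum, "diameter_mm")
                rho, p = bm.correlate(serum, "diameter_mm")
                manifest["biomarker"].update(
                    diameter_cutpoint_mm=cut, n_small=len(low),
                    n_large=len(high), spearman_rho=rho, spearman_p=p)
            log.info("biomarker: AUC %.3f", roc_result.auc)
        except Exception as exc:
            raise StageError(stage, exc) from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest
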