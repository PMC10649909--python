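"""End-to-end orchestration of the network-pharmacology stages.

Stages run in dependency order — chemical-space clustering, target
filtering/intersection, PPI hub ranking, enrichment, correlation screen,
descriptor ranking — each reading and writing plain TSV/JSON artifacts.
A stage whose (optional) inputs are absent is skipped with a warning; a
failing stage raises :class:`StageError` naming the stage.  All randomness
flows from the single configured seed, and identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import chemspace, descriptors, fingerprints, ppi_hub, stats, targets
from .synthetic import ConfigurationError, SimulationConfig, write_bundle
from .targets import GeneSet

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Input paths plus the fixed constants of the method.

    The defaults pin the method's published constants: radius-2 fingerprints
    at 2048 bits (similarity) and 1024 bits (embedding), the ``D_max/24``
    edge rule, top-10 hubs, enrichment cut-offs ``p = q = 0.01``, and the
    strict disease-score thresholds per source.
    """

    # inputs (None skips the stage that needs them)
    smiles_table: str | None = None
    fingerprint_table: str | None = None
    compound_targets: str | None = None
    disease_scores: str | None = None
    deg_table: str | None = None
    ppi_edges: str | None = None
    annotation: str | None = None
    universe: str | None = None
    expression: str | None = None
    expression_query: str | None = None
    descriptor_table: str | None = None
    # parameters
    seed: int = 0
    fp_radius: int = 2
    fp_bits_similarity: int = 2048
    fp_bits_embedding: int = 1024
    use_chirality: bool = False
    perplexity: float | None = None
    distance_divisor: float = 24.0
    embedding_source: str = "bits"  # "bits" (1024-bit vectors) or "dice" (2048-bit matrix)
    source_thresholds: dict[str, float | None] = field(
        default_factory=lambda: dict(targets.DEFAULT_SOURCE_THRESHOLDS)
    )
    deg_consensus_k: int = 3
    min_confidence: float = ppi_hub.DEFAULT_MIN_CONFIDENCE
    top_k: int = 10
    p_cutoff: float = 0.01
    q_cutoff: float = 0.01
    gap_tolerance: float = descriptors.DEFAULT_GAP_TOLERANCE
    outdir: str = "liconet_out"
    simulate: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.distance_divisor <= 0:
            raise ConfigurationError("distance_divisor must be positive")
        if self.embedding_source not in ("bits", "dice"):
            raise ConfigurationError("embedding_source must be 'bits' or 'dice'")
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.simulate)
        params.setdefault("seed", self.seed)
        return SimulationConfig(**params)

    def resolved(self) -> dict[str, Any]:
        return asdict(self)


def _outdir(config: PipelineConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"no {what} input configured")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} input not found: {p}")
    return p


def simulate(config: PipelineConfig) -> dict[str, Path]:
    """Write a synthetic input bundle (plus truth sidecar) into the outdir."""
    out = _outdir(config) / "synthetic"
    try:
        sim = config.simulation_config()
        return write_bundle(sim, out)
    except ConfigurationError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("simulate", exc) from exc


def _load_fingerprints(config: PipelineConfig) -> tuple[dict, dict]:
    """Similarity and embedding fingerprints from SMILES or a fingerprint table."""
    if config.smiles_table is not None:
        path = _require(config.smiles_table, "smiles_table")
        parsed = fingerprints.parse_smiles_table(path)
        for err in parsed.errors:
            logger.warning("[cluster] %s", err)
        sim_fps = {
            c.id: fingerprints.morgan_fingerprint(
                c, config.fp_radius, config.fp_bits_similarity, use_chirality=config.use_chirality
            )
            for c in parsed
        }
        emb_fps = {
            c.id: fingerprints.morgan_fingerprint(
                c, config.fp_radius, config.fp_bits_embedding, use_chirality=config.use_chirality
            )
            for c in parsed
        }
        return sim_fps, emb_fps
    path = _require(config.fingerprint_table, "fingerprint_table")
    fps = fingerprints.read_fingerprints(path)
    return fps, fps


def run_cluster(config: PipelineConfig) -> dict[str, Any]:
    """Fingerprints → embedding → chemical-space network → scored clusters."""
    try:
        out = _outdir(config)
        sim_fps, emb_fps = _load_fingerprints(config)
        sim = fingerprints.similarity_matrix(sim_fps)
        if config.embedding_source == "dice":
            distance = 1.0 - sim.values
            embedding = chemspace.embed_2d(
                emb_fps, config.seed, config.perplexity, distance=distance
            )
        else:
            embedding = chemspace.embed_2d(emb_fps, config.seed, config.perplexity)
        net = chemspace.build_csn(embedding, sim, divisor=config.distance_divisor)
        clusters = chemspace.cluster_components(net)
        chemspace.score_clusters(net, clusters, sim)
        report = chemspace.cluster_report(clusters)
        fingerprints.write_similarity_matrix(sim, out / "similarity.tsv")
        chemspace.write_embedding(embedding, out / "embedding.tsv")
        chemspace.write_network(net, out / "csn_edges.tsv", out / "csn.graphml")
        report.to_csv(out / "clusters.tsv", sep="\t", index=False)
        logger.info(
            "[cluster] %d compounds, %d clusters, theta=%.4g",
            len(sim.ids),
            len(clusters),
            net.theta,
        )
        return {
            "similarity": sim,
            "embedding": embedding,
            "network": net,
            "clusters": clusters,
            "report": report,
        }
    except (StageError,):
        raise
    except Exception as exc:
        raise StageError("cluster", exc) from exc


def run_targets(config: PipelineConfig) -> dict[str, Any]:
    """Score-filter disease genes, take the DEG consensus, intersect per compound."""
    try:
        out = _outdir(config)
        per_compound = targets.read_compound_targets(
            _require(config.compound_targets, "compound_targets")
        )
        scored = pd.read_csv(_require(config.disease_scores, "disease_scores"), sep="\t")
        disease = targets.filter_disease_genes(scored, config.source_thresholds)
        deg_df = pd.read_csv(_require(config.deg_table, "deg_table"), sep="\t")
        degs_by_dir = targets.consensus_deg(deg_df, k=config.deg_consensus_k)
        degs = GeneSet(
            genes=degs_by_dir["up"].genes | degs_by_dir["down"].genes, label="deg"
        )
        intersections = {
            comp: targets.compound_disease_intersection(gs, disease, degs)
            for comp, gs in per_compound.items()
        }
        core = (
            targets.common_core(list(intersections.values()))
            if len(intersections) >= 2
            else None
        )
        report = targets.intersection_report(per_compound, intersections)
        report.to_csv(out / "intersections.tsv", sep="\t", index=False)
        if core is not None:
            targets.write_gene_set(core, out / "core_genes.tsv")
        logger.info(
            "[targets] disease=%d deg=%d core=%s",
            len(disease),
            len(degs),
            "n/a" if core is None else len(core),
        )
        return {
            "per_compound": per_compound,
            "disease": disease,
            "degs": degs,
            "degs_by_direction": degs_by_dir,
            "intersections": intersections,
            "core": core,
        }
    except Exception as exc:
        raise StageError("targets", exc) from exc


def run_hubs(
    config: PipelineConfig, intersections: Mapping[str, GeneSet] | None = None
) -> dict[str, Any]:
    """MCC-rank the PPI graph, per compound where target sets are available."""
    try:
        out = _outdir(config)
        graph = ppi_hub.load_ppi(
            _require(config.ppi_edges, "ppi_edges"), config.min_confidence
        )
        result = ppi_hub.mcc_scores(graph)
        global_hubs = ppi_hub.top_k_hubs(result, config.top_k)
        per_compound_hubs: dict[str, list[str]] = {}
        if intersections:
            for comp, gs in intersections.items():
                nodes = [g for g in gs.genes if g in graph]
                if not nodes:
                    logger.warning("[hubs] no PPI nodes for %s; skipped", comp)
                    continue
                sub = ppi_hub.mcc_scores(graph.subgraph(nodes))
                per_compound_hubs[comp] = ppi_hub.top_k_hubs(sub, config.top_k)
        union = ppi_hub.hub_union(per_compound_hubs or {"all": global_hubs})
        ppi_hub.hub_report(result, global_hubs, union.provenance).to_csv(
            out / "hubs.tsv", sep="\t", index=False
        )
        targets.write_gene_set(union.genes, out / "hub_union.tsv")
        logger.info(
            "[hubs] graph %d nodes / %d edges, hub union %d genes",
            graph.number_of_nodes(),
            graph.number_of_edges(),
            len(union),
        )
        return {
            "graph": graph,
            "mcc": result,
            "global_hubs": global_hubs,
            "per_compound_hubs": per_compound_hubs,
            "union": union,
        }
    except Exception as exc:
        raise StageError("hubs", exc) from exc


def run_enrich(config: PipelineConfig, study: GeneSet) -> pd.DataFrame:
    """Hypergeometric over-representation of the study set, BH-adjusted."""
    try:
        out = _outdir(config)
        annotation = stats.read_annotation(_require(config.annotation, "annotation"))
        if config.universe is not None:
            universe = targets.read_gene_set(_require(config.universe, "universe"))
        else:
            universe = GeneSet(
                genes=frozenset().union(*(gs.genes for gs in annotation.values())),
                label="annotated",
            )
        table = stats.enrich(study, annotation, universe, config.p_cutoff, config.q_cutoff)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        logger.info(
            "[enrich] %d terms tested, %d significant", len(table), int(table["significant"].sum())
        )
        return table
    except Exception as exc:
        raise StageError("enrich", exc) from exc


def run_corr(config: PipelineConfig) -> pd.DataFrame:
    """Pearson correlation screen of all genes against the query gene."""
    try:
        out = _outdir(config)
        expr = stats.read_expression(_require(config.expression, "expression"))
        query = config.expression_query
        if query is None:
            raise ValueError("expression_query must name the query gene")
        screen = stats.correlation_screen(expr, query)
        screen.to_csv(out / "correlation_full.tsv", sep="\t", index=False)
        stats.correlation_table(screen).to_csv(out / "correlation.tsv", sep="\t", index=False)
        logger.info("[corr] %d genes screened against %s", len(screen), query)
        return screen
    except Exception as exc:
        raise StageError("corr", exc) from exc


def run_descriptors(config: PipelineConfig) -> dict[str, Any]:
    """Recompute HOMO–LUMO gaps, validate printed ones, rank by reactivity."""
    try:
        out = _outdir(config)
        # the sentinel "packaged" selects the bundled flavonoid table
        path = None if config.descriptor_table in (None, "packaged") else config.descriptor_table
        table = descriptors.load_descriptor_table(path)
        flagged = descriptors.validate_gaps(table, config.gap_tolerance)
        ranking = descriptors.reactivity_ranking(table)
        table.assign(rank=[ranking.index(c) + 1 for c in table["compound"]]).to_csv(
            out / "descriptors.tsv", sep="\t", index=False
        )
        logger.info("[descriptors] %d rows, %d gap discrepancies", len(table), len(flagged))
        return {"table": table, "flagged": flagged, "ranking": ranking}
    except Exception as exc:
        raise StageError("descriptors", exc) from exc


def run_full(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage whose inputs are configured; write ``summary.json``.

    The cluster, targets and descriptor stages are independent entry points;
    hubs consume the targets stage's intersections when available, and the
    enrichment study set is the union of per-compound intersections (falling
    back to the hub union, then to nothing — in which case the stage is
    skipped).
    """
    out = _outdir(config)
    summary: dict[str, Any] = {"seed": config.seed, "stages": {}}

    cluster_res = None
    if config.smiles_table or config.fingerprint_table:
        cluster_res = run_cluster(config)
        clusters = cluster_res["clusters"]
        summary["stages"]["cluster"] = {
            "n_compounds": len(cluster_res["similarity"].ids),
            "n_clusters": len(clusters),
            "cluster_sizes": [c.n for c in clusters],
            "representatives": [c.representative for c in clusters],
            "theta": cluster_res["network"].theta,
        }
    else:
        logger.warning("[cluster] no compound input configured; stage skipped")

    target_res = None
    if config.compound_targets and config.disease_scores and config.deg_table:
        target_res = run_targets(config)
        summary["stages"]["targets"] = {
            "n_disease": len(target_res["disease"]),
            "n_deg": len(target_res["degs"]),
            "intersection_sizes": {
                c: len(g) for c, g in target_res["intersections"].items()
            },
            "core_size": None if target_res["core"] is None else len(target_res["core"]),
            "core_genes": None
            if target_res["core"] is None
            else sorted(target_res["core"].genes),
        }
    else:
        logger.warning("[targets] inputs missing; stage skipped")

    hub_res = None
    if config.ppi_edges:
        hub_res = run_hubs(
            config, target_res["intersections"] if target_res else None
        )
        summary["stages"]["hubs"] = {
            "n_nodes": hub_res["graph"].number_of_nodes(),
            "n_edges": hub_res["graph"].number_of_edges(),
            "top_hubs": hub_res["global_hubs"],
            "hub_union_size": len(hub_res["union"]),
            "hub_union": sorted(hub_res["union"].genes.genes),
        }
    else:
        logger.warning("[hubs] no PPI input configured; stage skipped")

    if config.annotation:
        if target_res:
            study = GeneSet(
                genes=frozenset().union(
                    *(g.genes for g in target_res["intersections"].values())
                ),
                label="cross_targets",
            )
        elif hub_res:
            study = hub_res["union"].genes
        else:
            study = None
        if study is None:
            logger.warning("[enrich] no study set available; stage skipped")
        else:
            table = run_enrich(config, study)
            summary["stages"]["enrich"] = {
                "n_terms_tested": len(table),
                "n_significant": int(table["significant"].sum()),
                "top_term": None if table.empty else str(table.iloc[0]["term"]),
            }
    else:
        logger.warning("[enrich] no annotation configured; stage skipped")

    if config.expression:
        screen = run_corr(config)
        tested = screen[~screen["excluded"]]
        summary["stages"]["corr"] = {
            "n_genes": len(screen),
            "n_fdr_05": int((tested["fdr"] < 0.05).sum()),
            "top_genes": tested["gene"].head(5).tolist(),
        }
    else:
        logger.warning("[corr] no expression configured; stage skipped")

    if config.descriptor_table is not None:
        desc = run_descriptors(config)
        summary["stages"]["descriptors"] = {
            "n_rows": len(desc["table"]),
            "n_flagged": len(desc["flagged"]),
            "most_reactive": desc["ranking"][0],
            "least_reactive": desc["ranking"][-1],
        }

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True), encoding="utf-8"
    )
    return summary
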