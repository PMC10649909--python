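"""Synthetic inputs with planted ground truth for every pipeline stage.

The study's inputs are database exports (predicted compound targets, scored
disease genes, differential-expression calls, STRING edges, expression
matrices).  This module generates stand-ins for each of them with known
planted structure so the whole pipeline is testable offline:

* a fingerprint library with planted clusters — each cluster is a prototype
  bit vector (bits on with probability ``bit_density``) whose members flip
  every bit independently with probability ``flip_rate``; background
  compounds are fresh prototypes, keeping bit density matched;
* per-compound target gene sets sharing exactly a planted core, a scored
  disease table whose planted genes clear the source thresholds, and a
  three-method DEG table whose planted genes are called consistently;
* a PPI graph with a planted clique (on the first core genes) plus
  Erdős–Rényi noise edges;
* an expression matrix in which planted genes carry a chosen population
  correlation to a query gene (bivariate-normal construction), plus a term
  annotation with one planted over-represented term.

One global seed expands into independent per-stream child seeds (compounds,
genes, graph, expression, annotation), so enlarging one stream never
perturbs another.  Identical configs produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .fingerprints import Fingerprint, write_fingerprints
from .targets import GeneSet

logger = logging.getLogger(__name__)

_STREAMS = ("compounds", "genes", "graph", "expression", "annotation")


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


@dataclass
class SimulationConfig:
    """Defaults mirror the study's scale where it is stated, desk scale otherwise.

    Seven compounds with ~25-gene target sets sharing a 17-gene core (the
    published per-compound intersections are 21–28 genes around a 17-gene
    core); sparse 2048-bit fingerprints at low flip rate; a 6-clique planted
    in a 100-node interaction graph; a 5-fold over-represented term; and a
    planted co-expression correlation of 0.45, the magnitude of the top
    published query correlations.
    """

    seed: int = 0
    # compound library
    n_clusters: int = 10
    members_per_cluster: int = 8
    n_background: int = 20
    nbits: int = 2048
    bit_density: float = 0.02
    flip_rate: float = 0.01
    # gene tables
    n_compounds: int = 7
    gene_universe: int = 2000
    target_set_size: int = 25
    core_size: int = 17
    n_extra_disease: int = 300
    n_decoy_scores: int = 300
    n_extra_deg: int = 400
    n_decoy_deg: int = 200
    # PPI graph
    clique_size: int = 6
    n_ppi_nodes: int = 100
    noise_edge_prob: float = 0.01
    # annotation
    n_terms: int = 40
    term_size: int = 50
    enrichment_fold: float = 5.0
    # expression
    n_samples: int = 100
    n_expr_genes: int = 200
    n_corr_genes: int = 20
    planted_correlation: float = 0.45

    def __post_init__(self) -> None:
        probs = {
            "bit_density": self.bit_density,
            "flip_rate": self.flip_rate,
            "noise_edge_prob": self.noise_edge_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if abs(self.planted_correlation) > 1.0:
            raise ConfigurationError("planted_correlation must lie in [-1, 1]")
        positive = {
            "n_clusters": self.n_clusters,
            "members_per_cluster": self.members_per_cluster,
            "n_compounds": self.n_compounds,
            "gene_universe": self.gene_universe,
            "target_set_size": self.target_set_size,
            "n_terms": self.n_terms,
            "term_size": self.term_size,
            "n_expr_genes": self.n_expr_genes,
        }
        for name, v in positive.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        nonneg = {
            "n_background": self.n_background,
            "core_size": self.core_size,
            "n_extra_disease": self.n_extra_disease,
            "n_decoy_scores": self.n_decoy_scores,
            "n_extra_deg": self.n_extra_deg,
            "n_decoy_deg": self.n_decoy_deg,
            "n_corr_genes": self.n_corr_genes,
        }
        for name, v in nonneg.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {v}")
        if self.nbits < 64:
            raise ConfigurationError("nbits must be >= 64")
        if self.bit_density * self.nbits < 1:
            raise ConfigurationError("bit_density * nbits must be >= 1")
        if not self.core_size <= self.target_set_size <= self.gene_universe:
            raise ConfigurationError(
                "need core_size <= target_set_size <= gene_universe; "
                f"got {self.core_size} / {self.target_set_size} / {self.gene_universe}"
            )
        if self.clique_size < 2:
            raise ConfigurationError("clique_size must be >= 2")
        if self.clique_size > self.n_ppi_nodes:
            raise ConfigurationError("clique_size exceeds n_ppi_nodes")
        if self.n_ppi_nodes > self.gene_universe:
            raise ConfigurationError("n_ppi_nodes exceeds gene_universe")
        if self.n_samples < 4:
            raise ConfigurationError("n_samples must be >= 4")
        if self.n_corr_genes > self.n_expr_genes:
            raise ConfigurationError("n_corr_genes exceeds n_expr_genes")

    def rng(self, stream: str) -> np.random.Generator:
        """Child generator for one of the named streams."""
        if stream not in _STREAMS:
            raise KeyError(f"unknown stream {stream!r}; expected one of {_STREAMS}")
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS.index(stream)])


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _compound_labels(n: int) -> list[str]:
    return [f"CPD{i}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# compound library


@dataclass
class CompoundLibrary:
    """Fingerprints with planted cluster labels (−1 marks background)."""

    fingerprints: dict[str, Fingerprint]
    labels: dict[str, int]
    seed: int

    @property
    def ids(self) -> list[str]:
        return list(self.fingerprints)


def expected_intra_cluster_dice(bit_density: float, flip_rate: float) -> float:
    """Closed-form large-B expectation of Dice between two cluster members.

    Per bit, each member shows the prototype bit flipped independently with
    probability ε, so ``P(bit on) = ρ(1−ε) + (1−ρ)ε`` and
    ``P(on in both) = ρ(1−ε)² + (1−ρ)ε²``; the Dice ratio of expectations is
    ``2·P(both) / (2·P(on))``.
    """
    rho, eps = bit_density, flip_rate
    p_on = rho * (1 - eps) + (1 - rho) * eps
    p_both = rho * (1 - eps) ** 2 + (1 - rho) * eps**2
    return p_both / p_on


def gen_compound_library(config: SimulationConfig) -> CompoundLibrary:
    """Planted-cluster fingerprint library.

    ``n_clusters * members_per_cluster`` clustered records plus
    ``n_background`` singleton prototypes, in that order; ids are
    ``CL{k}M{j}`` for cluster members and ``BG{i}`` for background.
    """
    rng = config.rng("compounds")
    B, rho, eps = config.nbits, config.bit_density, config.flip_rate
    fps: dict[str, Fingerprint] = {}
    labels: dict[str, int] = {}
    for k in range(config.n_clusters):
        proto = rng.random(B) < rho
        for j in range(config.members_per_cluster):
            bits = proto ^ (rng.random(B) < eps)
            cid = f"CL{k}M{j:03d}"
            fps[cid] = Fingerprint(on_bits=frozenset(np.flatnonzero(bits).tolist()), nbits=B)
            labels[cid] = k
    for i in range(config.n_background):
        bits = rng.random(B) < rho
        cid = f"BG{i:03d}"
        fps[cid] = Fingerprint(on_bits=frozenset(np.flatnonzero(bits).tolist()), nbits=B)
        # each background prototype is its own singleton class
        labels[cid] = -(i + 1)
    return CompoundLibrary(fingerprints=fps, labels=labels, seed=config.seed)


# ---------------------------------------------------------------------------
# gene tables


@dataclass
class TargetTables:
    """Per-compound target sets plus the scored-disease and DEG tables."""

    compound_targets: dict[str, GeneSet]
    disease_scores: pd.DataFrame
    deg_table: pd.DataFrame
    universe: list[str]
    core: GeneSet
    disease: GeneSet
    deg_consensus: GeneSet
    seed: int


def gen_target_tables(config: SimulationConfig) -> TargetTables:
    """Gene tables in which the planted structure is exactly recoverable.

    Every per-compound target set contains the planted core plus distinct
    filler genes (a fix-up pass guarantees the all-compound intersection is
    *exactly* the core).  All planted target genes clear the disease score
    thresholds in at least one source and are called in a consistent
    direction by all three DE methods, so the three-way intersections
    recover the full target sets.
    """
    rng = config.rng("genes")
    universe = _gene_names(config.gene_universe)
    uni_arr = np.array(universe)
    core = rng.choice(uni_arr, size=config.core_size, replace=False).tolist()
    non_core = sorted(set(universe) - set(core))
    n_fill = config.target_set_size - config.core_size
    compounds = _compound_labels(config.n_compounds)

    fills: dict[str, set[str]] = {
        comp: set(rng.choice(np.array(non_core), size=n_fill, replace=False))
        for comp in compounds
    }
    if config.n_compounds > 1 and n_fill > 0:
        # guarantee the intersection is exactly the core: no filler gene may
        # appear in every compound's set
        while True:
            shared = set.intersection(*fills.values()) if fills else set()
            if not shared:
                break
            offender = sorted(shared)[0]
            pool = sorted(set(non_core) - fills[compounds[0]])
            fills[compounds[0]].discard(offender)
            fills[compounds[0]].add(str(rng.choice(np.array(pool))))
    targets = {
        comp: GeneSet.from_iterable(set(core) | fills[comp], label=comp) for comp in compounds
    }

    all_targets = sorted(set().union(*(t.genes for t in targets.values()))) if targets else []
    remaining = sorted(set(universe) - set(all_targets))
    extra_disease = rng.choice(np.array(remaining), size=min(config.n_extra_disease, len(remaining)), replace=False).tolist()
    disease_genes = sorted(set(all_targets) | set(extra_disease))

    sources = ("disgenet", "genecards", "pharmgkb")
    score_rows = []
    for gene in disease_genes:
        src = sources[int(rng.integers(len(sources)))]
        if src == "disgenet":
            score = float(np.round(rng.uniform(0.15, 0.95), 4))
        elif src == "genecards":
            score = float(np.round(rng.uniform(6.0, 60.0), 4))
        else:
            score = float(np.round(rng.uniform(0.0, 1.0), 4))
        score_rows.append({"gene": gene, "score": score, "source": src})
    decoy_pool = sorted(set(universe) - set(disease_genes))
    decoys = rng.choice(np.array(decoy_pool), size=min(config.n_decoy_scores, len(decoy_pool)), replace=False)
    for gene in decoys:
        # decoys score strictly below threshold, and never in pharmgkb
        # (pharmgkb keeps everything)
        if rng.random() < 0.5:
            score_rows.append(
                {"gene": str(gene), "score": float(np.round(rng.uniform(0.0, 0.0999), 4)), "source": "disgenet"}
            )
        else:
            score_rows.append(
                {"gene": str(gene), "score": float(np.round(rng.uniform(0.0, 4.999), 4)), "source": "genecards"}
            )
    disease_scores = pd.DataFrame(score_rows).sort_values(["gene", "source"], kind="mergesort").reset_index(drop=True)

    deg_pool = sorted(set(universe) - set(all_targets))
    extra_deg = rng.choice(np.array(deg_pool), size=min(config.n_extra_deg, len(deg_pool)), replace=False).tolist()
    deg_genes = sorted(set(all_targets) | set(extra_deg))
    deg_rows = []
    methods = ("edger", "deseq2", "limma")
    for gene in deg_genes:
        direction = "up" if rng.random() < 0.5 else "down"
        sign = 1.0 if direction == "up" else -1.0
        for method in methods:
            deg_rows.append(
                {
                    "gene": gene,
                    "log2fc": float(np.round(sign * rng.uniform(1.0, 4.0), 4)),
                    "pvalue": float(np.format_float_scientific(rng.uniform(1e-8, 1e-3), 4)),
                    "direction": direction,
                    "method": method,
                }
            )
    decoy_deg_pool = sorted(set(deg_pool) - set(extra_deg))
    decoy_deg = rng.choice(np.array(decoy_deg_pool), size=min(config.n_decoy_deg, len(decoy_deg_pool)), replace=False)
    for gene in decoy_deg:
        direction = "up" if rng.random() < 0.5 else "down"
        sign = 1.0 if direction == "up" else -1.0
        n_calls = int(rng.integers(1, 3))  # 1 or 2 methods: dropped at k=3
        for method in rng.choice(np.array(methods), size=n_calls, replace=False):
            deg_rows.append(
                {
                    "gene": str(gene),
                    "log2fc": float(np.round(sign * rng.uniform(1.0, 4.0), 4)),
                    "pvalue": float(np.format_float_scientific(rng.uniform(1e-8, 1e-3), 4)),
                    "direction": direction,
                    "method": str(method),
                }
            )
    deg_table = pd.DataFrame(deg_rows).sort_values(["gene", "method"], kind="mergesort").reset_index(drop=True)

    return TargetTables(
        compound_targets=targets,
        disease_scores=disease_scores,
        deg_table=deg_table,
        universe=universe,
        core=GeneSet.from_iterable(core, label="planted_core"),
        disease=GeneSet.from_iterable(disease_genes, label="planted_disease"),
        deg_consensus=GeneSet.from_iterable(deg_genes, label="planted_deg"),
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# PPI graph


@dataclass
class PlantedPPI:
    """Edge table with the planted clique members."""

    edges: pd.DataFrame
    clique: list[str]
    nodes: list[str]
    seed: int

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, combined_score=float(row.combined_score))
        return g


def gen_ppi_graph(config: SimulationConfig, nodes: Iterable[str] | None = None) -> PlantedPPI:
    """Clique of ``clique_size`` nodes plus Erdős–Rényi noise edges.

    The clique occupies the first ``clique_size`` node names; every other
    unordered pair (self-loops never) gains a noise edge with probability
    ``noise_edge_prob``.  Edge confidences are drawn uniformly in
    [0.4, 1.0), above the default STRING-style cut-off.
    """
    rng = config.rng("graph")
    if nodes is None:
        node_list = _gene_names(config.n_ppi_nodes)
    else:
        node_list = list(nodes)
    if config.clique_size > len(node_list):
        raise ConfigurationError("clique_size exceeds the node universe")
    clique = node_list[: config.clique_size]
    rows = []
    n = len(node_list)
    clique_set = set(clique)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = node_list[i], node_list[j]
            in_clique = a in clique_set and b in clique_set
            if in_clique or rng.random() < config.noise_edge_prob:
                rows.append(
                    {
                        "gene_a": a,
                        "gene_b": b,
                        "combined_score": float(np.round(rng.uniform(0.4, 1.0), 3)),
                    }
                )
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])
    return PlantedPPI(edges=edges, clique=clique, nodes=node_list, seed=config.seed)


# ---------------------------------------------------------------------------
# annotation


def gen_annotation(
    config: SimulationConfig, study: GeneSet, universe: Iterable[str]
) -> tuple[dict[str, GeneSet], str]:
    """Random term annotation with one planted over-represented term.

    The planted term draws ``enrichment_fold`` times the null-expected
    number of its genes from the study set; all other terms are uniform
    draws from the universe.  Returns the annotation and the planted term id.
    """
    rng = config.rng("annotation")
    uni = sorted(set(universe))
    study_genes = sorted(study.genes & set(uni))
    if not study_genes:
        raise ConfigurationError("study set shares no genes with the universe")
    K, N, n = config.term_size, len(uni), len(study_genes)
    k_planted = int(round(config.enrichment_fold * K * n / N))
    k_planted = max(1, min(k_planted, min(K, n)))
    annotation: dict[str, GeneSet] = {}
    planted_term = "TERM0000"
    non_study = sorted(set(uni) - set(study_genes))
    planted_genes = set(rng.choice(np.array(study_genes), size=k_planted, replace=False)) | set(
        rng.choice(np.array(non_study), size=K - k_planted, replace=False)
    )
    annotation[planted_term] = GeneSet.from_iterable(planted_genes, label=planted_term)
    for t in range(1, config.n_terms):
        term = f"TERM{t:04d}"
        genes = rng.choice(np.array(uni), size=K, replace=False)
        annotation[term] = GeneSet.from_iterable(genes, label=term)
    return annotation, planted_term


# ---------------------------------------------------------------------------
# expression


@dataclass
class PlantedExpression:
    """Samples × genes matrix, the query gene, and the correlated plant."""

    expr: pd.DataFrame
    query: str
    planted_genes: list[str]
    seed: int


def gen_expression_matrix(config: SimulationConfig) -> PlantedExpression:
    """Expression matrix with genes planted at a chosen correlation.

    The query column is standard normal across samples; each planted gene is
    ``ρ_g · q + sqrt(1 − ρ_g²) · z`` with independent normal *z* (exact
    population correlation ``ρ_g``); remaining genes are independent noise.
    """
    rng = config.rng("expression")
    S = config.n_samples
    q = rng.standard_normal(S)
    query = "QUERY"
    genes = [f"E{i:04d}" for i in range(1, config.n_expr_genes + 1)]
    planted = genes[: config.n_corr_genes]
    rho = config.planted_correlation
    data = {query: q}
    for gene in genes:
        if gene in planted:
            z = rng.standard_normal(S)
            data[gene] = rho * q + np.sqrt(1.0 - rho * rho) * z
        else:
            data[gene] = rng.standard_normal(S)
    expr = pd.DataFrame(data, index=[f"S{i:03d}" for i in range(1, S + 1)]).round(6)
    expr.index.name = "sample"
    return PlantedExpression(expr=expr, query=query, planted_genes=planted, seed=config.seed)


# ---------------------------------------------------------------------------
# bundle writer


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every input class and write the file bundle plus truth sidecar.

    The files use exactly the formats the pipeline readers consume, so a
    bundle is directly runnable end to end.  Returns the path of every
    artifact; ``truth.json`` records the planted ground truth and the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    library = gen_compound_library(config)
    paths["fingerprints"] = outdir / "fingerprints.tsv"
    write_fingerprints(library.fingerprints, paths["fingerprints"])

    tables = gen_target_tables(config)
    paths["compound_targets"] = outdir / "compound_targets.tsv"
    rows = [
        {"compound": comp, "gene": gene}
        for comp, gs in tables.compound_targets.items()
        for gene in sorted(gs.genes)
    ]
    pd.DataFrame(rows).to_csv(paths["compound_targets"], sep="\t", index=False)
    paths["disease_scores"] = outdir / "disease_scores.tsv"
    tables.disease_scores.to_csv(paths["disease_scores"], sep="\t", index=False)
    paths["deg_table"] = outdir / "deg_table.tsv"
    tables.deg_table.to_csv(paths["deg_table"], sep="\t", index=False)
    paths["universe"] = outdir / "universe.tsv"
    pd.DataFrame({"gene": tables.universe}).to_csv(paths["universe"], sep="\t", index=False)

    study = GeneSet.from_iterable(
        set().union(*(t.genes for t in tables.compound_targets.values())), label="study"
    )
    annotation, planted_term = gen_annotation(config, study, tables.universe)
    paths["annotation"] = outdir / "annotation.tsv"
    ann_rows = [
        {"term": term, "gene": gene}
        for term, gs in annotation.items()
        for gene in sorted(gs.genes)
    ]
    pd.DataFrame(ann_rows).to_csv(paths["annotation"], sep="\t", index=False)

    ppi_nodes = sorted(tables.core.genes)[: config.clique_size] + [
        g for g in _gene_names(config.gene_universe) if g not in tables.core.genes
    ][: config.n_ppi_nodes - config.clique_size]
    ppi = gen_ppi_graph(config, nodes=ppi_nodes)
    paths["ppi_edges"] = outdir / "ppi_edges.tsv"
    ppi.edges.to_csv(paths["ppi_edges"], sep="\t", index=False)

    expression = gen_expression_matrix(config)
    paths["expression"] = outdir / "expression.tsv"
    expression.expr.to_csv(paths["expression"], sep="\t")

    truth = {
        "seed": config.seed,
        "config": asdict(config),
        "cluster_labels": library.labels,
        "core_genes": sorted(tables.core.genes),
        "compound_targets": {c: sorted(g.genes) for c, g in tables.compound_targets.items()},
        "disease_genes": sorted(tables.disease.genes),
        "deg_genes": sorted(tables.deg_consensus.genes),
        "planted_clique": ppi.clique,
        "planted_term": planted_term,
        "expression_query": expression.query,
        "planted_corr_genes": expression.planted_genes,
        "planted_correlation": config.planted_correlation,
    }
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True), encoding="utf-8")
    return paths
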