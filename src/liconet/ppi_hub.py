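"""Maximal Clique Centrality (MCC) hub ranking on protein–protein networks.

MCC scores a node *v* as ``Σ_{C ∈ S(v)} (|C| − 1)!`` over the maximal
cliques *C* that contain *v*.  For a node whose neighbourhood induces no
edges this reduces to its degree, since each incident edge is then a maximal
2-clique contributing ``1! = 1``; an isolated node scores 0.  Hubs are the
top-k nodes by MCC with a deterministic lexicographic tie-break, and the
per-compound hub lists are unioned with provenance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .targets import GeneSet

logger = logging.getLogger(__name__)

#: STRING "medium confidence" default
DEFAULT_MIN_CONFIDENCE = 0.4


@dataclass
class MCCResult:
    """Per-node MCC scores plus the maximal-clique cover that produced them."""

    scores: dict[str, int]
    cliques: list[frozenset[str]]

    def cliques_of(self, node: str) -> list[frozenset[str]]:
        return [c for c in self.cliques if node in c]


def load_ppi(
    source: str | Path | pd.DataFrame,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> nx.Graph:
    """Read a STRING-style edge list into an undirected simple graph.

    Expects two node columns (``gene_a``/``gene_b`` or the first two
    columns) and an optional ``combined_score`` column; edges scoring below
    ``min_confidence`` are dropped, duplicates and reversed duplicates are
    collapsed, self-loops are discarded.  Malformed rows are skipped with a
    logged warning.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    g = nx.Graph()
    if df.empty:
        return g
    cols = list(df.columns)
    a_col = "gene_a" if "gene_a" in cols else cols[0]
    b_col = "gene_b" if "gene_b" in cols else cols[1]
    score_col = "combined_score" if "combined_score" in cols else (cols[2] if len(cols) > 2 else None)
    for rowno, row in enumerate(df.itertuples(index=False), start=1):
        a = getattr(row, a_col, None)
        b = getattr(row, b_col, None)
        if not isinstance(a, str) or not isinstance(b, str) or not a or not b:
            logger.warning("ppi row %d malformed; skipped", rowno)
            continue
        a, b = a.strip().upper(), b.strip().upper()
        if a == b:
            continue
        if score_col is not None:
            try:
                score = float(getattr(row, score_col))
            except (TypeError, ValueError):
                logger.warning("ppi row %d has unreadable score; skipped", rowno)
                continue
            if score < min_confidence:
                continue
            g.add_edge(a, b, combined_score=score)
        else:
            g.add_edge(a, b)
    return g


def maximal_cliques(g: nx.Graph) -> list[frozenset[str]]:
    """All maximal cliques (Bron–Kerbosch with pivoting), each reported once.

    Singleton "cliques" of isolated nodes are excluded: only cliques on at
    least one edge contribute to MCC.
    """
    return sorted(
        (frozenset(c) for c in nx.find_cliques(g) if len(c) >= 2),
        key=lambda c: (sorted(c)),
    )


def mcc_scores(g: nx.Graph) -> MCCResult:
    """MCC of every node: ``Σ (|C| − 1)!`` over maximal cliques containing it."""
    cliques = maximal_cliques(g)
    scores: dict[str, int] = {v: 0 for v in g.nodes}
    for clique in cliques:
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return MCCResult(scores=scores, cliques=cliques)


def top_k_hubs(result: MCCResult, k: int = 10) -> list[str]:
    """Nodes ranked by descending MCC, ties lexicographic, truncated at *k*."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(result.scores, key=lambda v: (-result.scores[v], v))
    if len(ranked) < k:
        logger.warning("requested top %d hubs but graph has only %d nodes", k, len(ranked))
    return ranked[:k]


@dataclass
class HubUnion:
    """Union of per-compound hub lists with per-gene provenance."""

    genes: GeneSet
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def hub_union(per_compound: Mapping[str, Sequence[str]] | Sequence[Sequence[str]]) -> HubUnion:
    """Set union of all ranked hub lists, recording which compounds contributed."""
    if not isinstance(per_compound, Mapping):
        per_compound = {str(i): lst for i, lst in enumerate(per_compound)}
    if not per_compound:
        raise ValueError("hub union requires at least one hub list")
    provenance: dict[str, list[str]] = {}
    for comp, hubs in per_compound.items():
        for gene in hubs:
            provenance.setdefault(str(gene).upper(), []).append(str(comp))
    return HubUnion(
        genes=GeneSet(genes=frozenset(provenance), label="hub_union"),
        provenance=provenance,
    )


def hub_report(result: MCCResult, hubs: Sequence[str], provenance: Mapping[str, Sequence[str]] | None = None) -> pd.DataFrame:
    rows = [
        {
            "gene": gene,
            "mcc": result.scores.get(gene, 0),
            "rank": rank,
            "compounds": ",".join(provenance.get(gene, [])) if provenance else "",
        }
        for rank, gene in enumerate(hubs, start=1)
    ]
    return pd.DataFrame(rows, columns=["gene", "mcc", "rank", "compounds"])
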