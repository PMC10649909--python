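"""Chemical-space-network clustering of compound libraries.

The method embeds compounds into two dimensions with t-SNE over the
``1 - Dice`` fingerprint distance, then joins every pair of compounds whose
embedded Euclidean distance falls below a global threshold
``θ = D_max / 24``, where ``D_max`` is the largest embedded distance in the
library.  Connected components of the resulting graph are the clusters.
Within each cluster two member scores are computed:

* mean within-group similarity ``MWGS_i = (Σ_j S_ij − 1) / n`` — the sum of
  member *i*'s Dice similarities over the whole group (the self term equals
  1 and is subtracted) divided by the group size;
* closeness centrality on the full network, Wasserman–Faust scaled,
  ``((k−1)/(N−1)) · ((k−1)/Σd)`` with *k* the size of the member's connected
  component and *N* the network size, so values are comparable across
  components and bounded by 1.

The member with the maximum closeness is the cluster representative (ties
broken by MWGS, then id); the maximum-MWGS member is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .fingerprints import Fingerprint, SimilarityMatrix, similarity_matrix

logger = logging.getLogger(__name__)

DISTANCE_DIVISOR = 24.0


@dataclass
class Embedding2D:
    """2-D t-SNE coordinates per compound, with the seed that produced them."""

    coords: dict[str, tuple[float, float]]
    seed: int
    perplexity: float

    def __len__(self) -> int:
        return len(self.coords)

    def array(self, ids: Sequence[str] | None = None) -> np.ndarray:
        ids = list(self.coords) if ids is None else list(ids)
        return np.array([self.coords[i] for i in ids], dtype=float)


@dataclass
class ChemSpaceNetwork:
    """Thresholded proximity graph over embedded compounds.

    Nodes carry ``x``/``y`` coordinates; edges exist for embedded distance
    ``d < θ`` and carry ``distance`` and ``dice`` attributes.
    """

    graph: nx.Graph
    d_max: float
    theta: float
    divisor: float = DISTANCE_DIVISOR

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)


@dataclass
class Cluster:
    """A connected component of the chemical-space network."""

    members: list[str]
    mwgs: dict[str, float] = field(default_factory=dict)
    closeness: dict[str, float] = field(default_factory=dict)
    representative: str | None = None
    representative_mwgs: str | None = None

    @property
    def n(self) -> int:
        return len(self.members)


def default_perplexity(n: int) -> float:
    """``min(30, (n − 1) / 3)`` — keeps t-SNE well-posed for small libraries."""
    return min(30.0, (n - 1) / 3.0)


def embed_2d(
    fps: Mapping[str, Fingerprint],
    seed: int,
    perplexity: float | None = None,
    *,
    distance: np.ndarray | None = None,
    max_iter: int = 5000,
) -> Embedding2D:
    """t-SNE embedding of fingerprints into the plane.

    The pairwise distance is ``1 - Dice`` computed from ``fps`` (pass a
    precomputed square ``distance`` matrix to override, e.g. to embed from
    the 2048-bit similarity matrix instead of the 1024-bit vectors).
    Identical seeds give identical coordinates.
    """
    ids = list(fps.keys())
    n = len(ids)
    if n < 3:
        raise ValueError(f"embedding requires at least 3 compounds, got {n}")
    if perplexity is None:
        perplexity = default_perplexity(n)
    if not perplexity < n:
        raise ValueError(f"perplexity ({perplexity}) must be < n ({n})")
    if distance is None:
        sim = similarity_matrix(fps)
        distance = 1.0 - sim.values
        np.fill_diagonal(distance, 0.0)
    distance = np.asarray(distance, dtype=float)
    if distance.shape != (n, n):
        raise ValueError("distance matrix shape does not match compound count")
    # the exact gradient and a long iteration budget matter here: the D_max/24
    # edge rule downstream needs near-duplicate compounds to collapse to a
    # small fraction of the global extent, which the default 1000 iterations
    # do not reliably reach on small libraries
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        random_state=seed,
        perplexity=perplexity,
        method="exact",
        max_iter=max_iter,
    )
    xy = tsne.fit_transform(distance)
    coords = {cid: (float(x), float(y)) for cid, (x, y) in zip(ids, xy)}
    return Embedding2D(coords=coords, seed=seed, perplexity=float(perplexity))


def build_csn(
    embedding: Embedding2D,
    sim: SimilarityMatrix,
    divisor: float = DISTANCE_DIVISOR,
) -> ChemSpaceNetwork:
    """Threshold graph over embedded compounds.

    Computes ``D_max`` (largest pairwise embedded distance) and joins every
    pair strictly closer than ``θ = D_max / divisor``; each edge carries the
    embedded distance and the Dice similarity of its endpoints.
    """
    ids = list(embedding.coords)
    if len(ids) < 2:
        raise ValueError("network construction requires at least 2 compounds")
    if set(ids) != set(sim.ids):
        raise ValueError("embedding and similarity matrix cover different compounds")
    if divisor <= 0:
        raise ValueError("distance divisor must be positive")
    xy = embedding.array(ids)
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    d_max = float(dist.max())
    theta = d_max / divisor
    simdf = sim.to_frame()
    g = nx.Graph()
    for cid in ids:
        x, y = embedding.coords[cid]
        g.add_node(cid, x=x, y=y)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < theta:
                g.add_edge(
                    ids[i],
                    ids[j],
                    distance=float(dist[i, j]),
                    dice=float(simdf.at[ids[i], ids[j]]),
                )
    return ChemSpaceNetwork(graph=g, d_max=d_max, theta=theta, divisor=divisor)


def cluster_components(net: ChemSpaceNetwork) -> list[Cluster]:
    """Connected components of the network, ordered by smallest member id."""
    comps = [sorted(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: c[0])
    return [Cluster(members=c) for c in comps]


def mwgs_scores(cluster: Cluster, sim: SimilarityMatrix) -> dict[str, float]:
    """Mean within-group similarity ``(Σ_j S_ij − 1) / n`` per member.

    The sum runs over all group members including the member itself, whose
    self-similarity of 1 is subtracted; a singleton therefore scores 0.
    """
    simdf = sim.to_frame()
    missing = [m for m in cluster.members if m not in simdf.index]
    if missing:
        raise KeyError(f"cluster members missing from similarity matrix: {missing}")
    n = cluster.n
    scores = {
        m: (float(simdf.loc[m, cluster.members].sum()) - 1.0) / n for m in cluster.members
    }
    cluster.mwgs = scores
    return scores


def closeness_scores(net: ChemSpaceNetwork, cluster: Cluster) -> dict[str, float]:
    """Wasserman–Faust closeness of each member, computed on the full network.

    ``((k−1)/(N−1)) · ((k−1)/Σd)`` where *k* counts nodes reachable from the
    member and Σd sums shortest-path lengths to them; isolated members score 0.
    """
    missing = [m for m in cluster.members if m not in net.graph]
    if missing:
        raise KeyError(f"cluster members missing from network: {missing}")
    scores = {
        m: float(nx.closeness_centrality(net.graph, u=m, wf_improved=True))
        for m in cluster.members
    }
    cluster.closeness = scores
    return scores


def select_representative(cluster: Cluster) -> str:
    """Member with maximal closeness; ties broken by MWGS, then smallest id.

    Also records the maximal-MWGS member on the cluster, since the method
    description nominates representatives both ways.
    """
    if not cluster.closeness or not cluster.mwgs:
        raise ValueError("compute mwgs_scores and closeness_scores before selecting")
    rep = min(
        cluster.members,
        key=lambda m: (-cluster.closeness[m], -cluster.mwgs[m], m),
    )
    rep_mwgs = min(cluster.members, key=lambda m: (-cluster.mwgs[m], m))
    cluster.representative = rep
    cluster.representative_mwgs = rep_mwgs
    return rep


def score_clusters(
    net: ChemSpaceNetwork, clusters: Sequence[Cluster], sim: SimilarityMatrix
) -> None:
    """Fill MWGS, closeness and representatives on every cluster in place."""
    for c in clusters:
        mwgs_scores(c, sim)
        closeness_scores(net, c)
        select_representative(c)


# ---------------------------------------------------------------------------
# file I/O


def write_embedding(embedding: Embedding2D, path: str | Path) -> None:
    rows = [
        {"id": cid, "x": x, "y": y, "seed": embedding.seed}
        for cid, (x, y) in embedding.coords.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_network(net: ChemSpaceNetwork, edge_path: str | Path, graphml_path: str | Path | None = None) -> None:
    rows = [
        {"source": u, "target": v, "distance": d["distance"], "dice": d["dice"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    cols = ["source", "target", "distance", "dice"]
    pd.DataFrame(rows, columns=cols).to_csv(edge_path, sep="\t", index=False)
    if graphml_path is not None:
        g = net.graph.copy()
        g.graph.update(d_max=net.d_max, theta=net.theta, divisor=net.divisor)
        nx.write_graphml(g, graphml_path)


def cluster_report(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """One row per compound: cluster id, scores and representative flags."""
    rows = []
    for k, c in enumerate(clusters):
        for m in c.members:
            rows.append(
                {
                    "compound": m,
                    "cluster": k,
                    "cluster_size": c.n,
                    "mwgs": c.mwgs.get(m, float("nan")),
                    "closeness": c.closeness.get(m, float("nan")),
                    "is_representative": m == c.representative,
                    "is_mwgs_representative": m == c.representative_mwgs,
                }
            )
    return pd.DataFrame(rows)
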