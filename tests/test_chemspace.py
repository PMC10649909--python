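"""Embedding, threshold-network construction, clustering and member scores."""

import math

import networkx as nx
import numpy as np
import pytest

from liconet.chemspace import (
    ChemSpaceNetwork,
    Cluster,
    Embedding2D,
    build_csn,
    closeness_scores,
    cluster_components,
    embed_2d,
    mwgs_scores,
    select_representative,
)
from liconet.fingerprints import Fingerprint, SimilarityMatrix, morgan_fingerprint, similarity_matrix


def make_embedding(coords, seed=0):
    return Embedding2D(coords={k: tuple(map(float, v)) for k, v in coords.items()}, seed=seed, perplexity=5.0)


def make_network(nodes, edges, theta=1.0):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return ChemSpaceNetwork(graph=g, d_max=theta * 24, theta=theta)


def uniform_sim(ids, value=0.5):
    n = len(ids)
    m = np.full((n, n), value)
    np.fill_diagonal(m, 1.0)
    return SimilarityMatrix(ids=list(ids), values=m)


class TestEmbed2D:
    def test_one_coordinate_per_compound(self, flavonoid_compounds):
        fps = {c.id: morgan_fingerprint(c, nbits=1024) for c in flavonoid_compounds}
        emb = embed_2d(fps, seed=0)
        assert set(emb.coords) == set(fps)
        assert all(np.isfinite(v).all() for v in map(np.asarray, emb.coords.values()))

    def test_same_seed_gives_identical_coordinates(self, flavonoid_compounds):
        fps = {c.id: morgan_fingerprint(c, nbits=1024) for c in flavonoid_compounds}
        a = embed_2d(fps, seed=3)
        b = embed_2d(fps, seed=3)
        assert a.coords == b.coords

    def test_too_few_compounds_rejected(self):
        fps = {"a": Fingerprint(frozenset({1}), 64), "b": Fingerprint(frozenset({2}), 64)}
        with pytest.raises(ValueError, match="at least 3"):
            embed_2d(fps, seed=0)

    def test_perplexity_must_be_below_n(self, flavonoid_compounds):
        fps = {c.id: morgan_fingerprint(c, nbits=1024) for c in flavonoid_compounds}
        with pytest.raises(ValueError, match="perplexity"):
            embed_2d(fps, seed=0, perplexity=10)

    def test_duplicate_compounds_embed_close(self):
        """A Dice-identical pair among 20 lands below the 5th percentile of
        pairwise distances in at least 95% of seeds."""
        rng = np.random.default_rng(0)
        base = [frozenset(np.flatnonzero(rng.random(1024) < 0.05).tolist()) for _ in range(19)]
        bits = base + [base[0]]  # ids s19 duplicates s0
        fps = {f"s{i}": Fingerprint(b, 1024) for i, b in enumerate(bits)}
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            emb = embed_2d(fps, seed=seed)
            xy = emb.array()
            d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
            pair = d[0, 19]
            upper = np.triu_indices(20, k=1)
            hits += pair <= np.percentile(d[upper], 5)
        assert hits >= 0.95 * n_seeds


class TestBuildCSN:
    def test_two_points_at_distance_24_have_no_edge(self):
        emb = make_embedding({"a": (0, 0), "b": (24, 0)})
        net = build_csn(emb, uniform_sim(["a", "b"]))
        assert net.theta == pytest.approx(1.0)
        assert net.edges == []

    def test_unit_square_has_no_edges(self):
        emb = make_embedding({"a": (0, 0), "b": (1, 0), "c": (1, 1), "d": (0, 1)})
        net = build_csn(emb, uniform_sim("abcd"))
        assert net.d_max == pytest.approx(math.sqrt(2))
        assert net.theta == pytest.approx(math.sqrt(2) / 24)
        assert net.edges == []

    def test_edges_match_brute_force_all_pairs_check(self):
        rng = np.random.default_rng(42)
        ids = [f"c{i}" for i in range(50)]
        xy = rng.uniform(0, 10, size=(50, 2))
        emb = make_embedding(dict(zip(ids, xy)))
        sim = uniform_sim(ids)
        net = build_csn(emb, sim)
        # independent O(n^2) oracle
        dmax = max(
            math.dist(xy[i], xy[j]) for i in range(50) for j in range(i + 1, 50)
        )
        theta = dmax / 24
        expected = {
            frozenset((ids[i], ids[j]))
            for i in range(50)
            for j in range(i + 1, 50)
            if math.dist(xy[i], xy[j]) < theta
        }
        assert {frozenset(e) for e in net.edges} == expected
        for _, _, data in net.graph.edges(data=True):
            assert data["dice"] == 0.5

    def test_single_point_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_csn(make_embedding({"a": (0, 0)}), uniform_sim(["a"]))


class TestClusterComponents:
    def test_edgeless_network_gives_singletons(self):
        net = make_network("abcde", [])
        clusters = cluster_components(net)
        assert [c.members for c in clusters] == [["a"], ["b"], ["c"], ["d"], ["e"]]

    def test_path_is_transitively_one_cluster(self):
        net = make_network("abc", [("a", "b"), ("b", "c")])
        clusters = cluster_components(net)
        assert [c.members for c in clusters] == [["a", "b", "c"]]

    def test_partition_invariant_to_node_insertion_order(self):
        rng = np.random.default_rng(1)
        nodes = [f"n{i}" for i in range(30)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(30)
            for j in range(i + 1, 30)
            if rng.random() < 0.05
        ]
        parts = []
        for order_seed in (0, 1):
            shuffled = list(nodes)
            np.random.default_rng(order_seed).shuffle(shuffled)
            g = nx.Graph()
            g.add_nodes_from(shuffled)
            g.add_edges_from(edges)
            net = ChemSpaceNetwork(graph=g, d_max=1.0, theta=1.0)
            parts.append({frozenset(c.members) for c in cluster_components(net)})
        assert parts[0] == parts[1]


class TestMWGS:
    def test_singleton_scores_zero(self):
        c = Cluster(members=["a"])
        scores = mwgs_scores(c, uniform_sim(["a"]))
        assert scores == {"a": 0.0}

    def test_pair_with_dice_08(self):
        m = np.array([[1.0, 0.8], [0.8, 1.0]])
        sim = SimilarityMatrix(ids=["a", "b"], values=m)
        scores = mwgs_scores(Cluster(members=["a", "b"]), sim)
        assert scores["a"] == pytest.approx(0.4) and scores["b"] == pytest.approx(0.4)

    def test_triple_matches_hand_substitution(self):
        # pairwise Dice: ab=0.9, ac=0.8, bc=0.7
        m = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.7], [0.8, 0.7, 1.0]])
        sim = SimilarityMatrix(ids=["a", "b", "c"], values=m)
        scores = mwgs_scores(Cluster(members=["a", "b", "c"]), sim)
        assert scores["a"] == pytest.approx((1 + 0.9 + 0.8 - 1) / 3, abs=1e-12)
        assert scores["b"] == pytest.approx((0.9 + 1 + 0.7 - 1) / 3, abs=1e-12)
        assert scores["c"] == pytest.approx((0.8 + 0.7 + 1 - 1) / 3, abs=1e-12)

    def test_missing_member_raises(self):
        with pytest.raises(KeyError):
            mwgs_scores(Cluster(members=["a", "zz"]), uniform_sim(["a"]))

    def test_upper_bound_reached_only_for_all_identical(self):
        n = 4
        sim_equal = uniform_sim(list("abcd"), value=1.0)
        scores = mwgs_scores(Cluster(members=list("abcd")), sim_equal)
        assert all(v == pytest.approx((n - 1) / n) for v in scores.values())
        sim_below = uniform_sim(list("abcd"), value=0.99)
        scores = mwgs_scores(Cluster(members=list("abcd")), sim_below)
        assert all(v < (n - 1) / n for v in scores.values())


def bfs_closeness_oracle(g, node):
    """Independent Wasserman-Faust closeness via explicit BFS."""
    dist = nx.single_source_shortest_path_length(g, node)
    k = len(dist)
    if k <= 1:
        return 0.0
    total = sum(dist.values())
    n = g.number_of_nodes()
    return ((k - 1) / (n - 1)) * ((k - 1) / total)


class TestCloseness:
    def test_path_p3(self):
        net = make_network("abc", [("a", "b"), ("b", "c")])
        c = Cluster(members=["a", "b", "c"])
        scores = closeness_scores(net, c)
        assert scores["b"] == pytest.approx(1.0)
        assert scores["a"] == pytest.approx(2 / 3)
        assert scores["c"] == pytest.approx(2 / 3)

    def test_isolated_node_scores_zero(self):
        net = make_network("ab", [])
        scores = closeness_scores(net, Cluster(members=["a"]))
        assert scores["a"] == 0.0

    def test_star_k14(self):
        net = make_network("cabde", [("c", x) for x in "abde"])
        scores = closeness_scores(net, Cluster(members=list("cabde")))
        assert scores["c"] == pytest.approx(1.0)
        for leaf in "abde":
            assert scores[leaf] == pytest.approx(4 / 7)

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            g = nx.gnp_random_graph(12, 0.25, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
            net = ChemSpaceNetwork(graph=g, d_max=1.0, theta=1.0)
            members = sorted(g.nodes)
            scores = closeness_scores(net, Cluster(members=members))
            for m in members:
                assert scores[m] == pytest.approx(bfs_closeness_oracle(g, m), abs=1e-12)
                assert 0.0 <= scores[m] <= 1.0


class TestRepresentative:
    def test_strict_maximum_closeness_wins(self):
        c = Cluster(
            members=["a", "b"],
            mwgs={"a": 0.1, "b": 0.9},
            closeness={"a": 0.8, "b": 0.5},
        )
        assert select_representative(c) == "a"

    def test_singleton_is_its_own_representative(self):
        c = Cluster(members=["x"], mwgs={"x": 0.0}, closeness={"x": 0.0})
        assert select_representative(c) == "x"

    def test_closeness_tie_broken_by_mwgs(self):
        c = Cluster(
            members=["a", "b"],
            mwgs={"a": 0.4, "b": 0.5},
            closeness={"a": 0.7, "b": 0.7},
        )
        assert select_representative(c) == "b"

    def test_mwgs_representative_recorded(self):
        c = Cluster(
            members=["a", "b"],
            mwgs={"a": 0.1, "b": 0.9},
            closeness={"a": 0.8, "b": 0.5},
        )
        select_representative(c)
        assert c.representative_mwgs == "b"
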