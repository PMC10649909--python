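"""Independent brute-force oracles shared by the unit and acceptance suites.

Everything here is deliberately naive — exhaustive enumeration, explicit
set arithmetic — and never calls the implementation paths it checks.
"""

import itertools
from fractions import Fraction
from math import comb, factorial

import networkx as nx


def exhaustive_maximal_cliques(g: nx.Graph) -> set[frozenset]:
    """All maximal cliques by checking every vertex subset (graphs <= ~14 nodes)."""
    nodes = list(g.nodes)
    cliques = []
    for r in range(2, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in itertools.combinations(subset, 2)):
                cliques.append(frozenset(subset))
    maximal = {
        c for c in cliques if not any(c < other for other in cliques)
    }
    return maximal


def exhaustive_mcc(g: nx.Graph) -> dict:
    """MCC per node from the exhaustive clique enumeration."""
    scores = {v: 0 for v in g.nodes}
    for clique in exhaustive_maximal_cliques(g):
        for v in clique:
            scores[v] += factorial(len(clique) - 1)
    return scores


def enumerate_hypergeom_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by enumerating every n-subset of an N-element universe.

    The first K elements are 'annotated'; a draw counts when it hits at
    least k of them.  Exact rational arithmetic; feasible for N <= 12.
    """
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if sum(1 for x in draw if x < K) >= k
    )
    return Fraction(hits, comb(N, n))


def stepup_bh(pvals):
    """BH step-up by the textbook formula with an explicit cummin loop."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        q[i] = running
    return q
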