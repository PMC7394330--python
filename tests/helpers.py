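"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: modularity is summed
straight from the adjacency definition, hypergeometric tails from exact
big-integer combinatorics, and Wang S-values from exhaustive root-ward path
enumeration.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Iterable, Iterator

import networkx as nx


def set_partitions(items: list) -> Iterator[list[list]]:
    """All partitions of a set, by recursive insertion."""
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in set_partitions(items[1:]):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
        yield [[first]] + smaller


def modularity_adjacency(g: nx.Graph, assignment: dict, weighted: bool = False) -> float:
    """Q = (1/2m) Σ_uv (A_uv − k_u k_v / 2m) δ(c_u, c_v), summed over ordered pairs."""
    def w(u, v):
        if not g.has_edge(u, v):
            return 0.0
        return g[u][v].get("weight", 1.0) if weighted else 1.0

    nodes = list(g.nodes)
    k = {u: sum(w(u, v) for v in g[u]) for u in nodes}
    m2 = sum(k.values())
    q = 0.0
    for u in nodes:
        for v in nodes:
            if assignment[u] == assignment[v]:
                q += w(u, v) - k[u] * k[v] / m2
    return q / m2


def best_partition_bruteforce(g: nx.Graph) -> float:
    """Globally maximal modularity over every partition of the node set."""
    nodes = list(g.nodes)
    best = -2.0
    for part in set_partitions(nodes):
        assignment = {u: i for i, group in enumerate(part) for u in group}
        q = modularity_adjacency(g, assignment)
        if q > best:
            best = q
    return best


def hypergeom_upper_tail_exact(n_f: int, N: int, K_term: int, U: int) -> Fraction:
    """P[X >= n_f] by direct big-integer pmf summation."""
    denom = comb(U, N)
    total = 0
    for k in range(n_f, min(N, K_term) + 1):
        total += comb(K_term, k) * comb(U - K_term, N - k)
    return Fraction(total, denom)


def wang_svalues_by_paths(term: str, dag, w_is_a: float = 0.8, w_part_of: float = 0.6) -> dict:
    """S-values via exhaustive enumeration of root-ward paths term → ancestor.

    S(t) is the maximum over all directed paths from the term to t of the
    product of the edge factors along the path.
    """
    wmap = {"is_a": w_is_a, "part_of": w_part_of}
    out = {term: 1.0}

    def walk(node: str, value: float) -> None:
        for parent in dag.graph.successors(node):
            v = value * wmap[dag.graph.edges[node, parent]["relation"]]
            if v > out.get(parent, 0.0):
                out[parent] = v
            walk(parent, v)

    walk(term, 1.0)
    return out


def adjusted_rand_index(labels_a: Iterable, labels_b: Iterable) -> float:
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(list(labels_a), list(labels_b)))
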