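"""Topological module detection by modularity optimization.

Modularity of a partition is Q = Σ_i (e_ii − a_i²), where e_ii is the fraction
of edge weight inside module i and a_i the fraction of edge endpoints attached
to module i.  Louvain greedily maximizes Q in two alternating phases (local
node moves, then graph aggregation).  Incremental Louvain re-applies Louvain
to any module larger than a size threshold, mitigating the resolution limit of
plain modularity maximization.
"""

from __future__ import annotations

import random
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .network import ProteinNetwork

#: modularity gains at or below this are treated as zero (no move).
GAIN_EPS = 1e-12


@dataclass
class ModulePartition:
    """Disjoint assignment of network nodes to modules.

    ``assignment`` maps node → module identifier (a string; Incremental
    Louvain identifiers record lineage, e.g. ``"3.1.2"``).
    """

    assignment: dict[str, str]
    modularity: float
    method: str
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def modules(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for node, mod in self.assignment.items():
            out[mod].add(node)
        return dict(out)

    @property
    def sizes(self) -> dict[str, int]:
        return {m: len(ns) for m, ns in self.modules.items()}


@dataclass
class ModuleSizeDistribution:
    """Module-size histogram with the mesoscale count (sizes strictly > threshold)."""

    sizes: list[int]
    mesoscale_threshold: int
    mesoscale_count: int
    mesoscale_fraction: float


def _edge_weight(d: Mapping, use_weights: bool) -> float:
    return float(d.get("weight", 1.0)) if use_weights else 1.0


def modularity(net: ProteinNetwork, assignment: Mapping[str, str], use_weights: bool = False) -> float:
    """Modularity Q = Σ_i (e_ii − a_i²) of a node→module assignment."""
    missing = net.nodes - set(assignment)
    if missing:
        raise ValueError(f"nodes missing from assignment: {sorted(missing)[:5]}")
    m2 = sum(2.0 * _edge_weight(d, use_weights) for _, _, d in net.graph.edges(data=True))
    if m2 == 0:
        raise ValueError("modularity undefined on a network with zero total edge weight")
    intra: dict[str, float] = defaultdict(float)
    deg: dict[str, float] = defaultdict(float)
    for u, v, d in net.graph.edges(data=True):
        w = _edge_weight(d, use_weights)
        cu, cv = assignment[u], assignment[v]
        if cu == cv:
            intra[cu] += w
        deg[cu] += w
        deg[cv] += w
    q = 0.0
    for c in set(assignment.values()):
        q += 2.0 * intra.get(c, 0.0) / m2 - (deg.get(c, 0.0) / m2) ** 2
    return q


def _one_level(g: nx.Graph, m2: float, rng: random.Random) -> tuple[dict, bool]:
    """Louvain local-moving phase on (possibly aggregated) graph ``g``.

    Each node starts in its own community; sweeps continue until a full pass
    makes no move.  Ties on modularity gain go to the smallest community
    identifier.  Returns (community map, whether anything moved).
    """
    comm = {u: u for u in g}
    k = {}
    for u in g:
        s = 0.0
        for v, d in g[u].items():
            s += d.get("weight", 1.0) * (2.0 if v == u else 1.0)
        k[u] = s
    sigma_tot = dict(k)
    moved_any = False
    while True:
        n_moves = 0
        order = sorted(g.nodes)
        rng.shuffle(order)
        for u in order:
            cu = comm[u]
            nbr_w: dict = defaultdict(float)
            for v, d in g[u].items():
                if v != u:
                    nbr_w[comm[v]] += d.get("weight", 1.0)
            sigma_tot[cu] -= k[u]
            # gain (up to the constant 2/m2 factor) of joining community c
            def gain(c: object) -> float:
                return nbr_w.get(c, 0.0) - sigma_tot[c] * k[u] / m2
            best_c, best_g = cu, gain(cu)
            for c in sorted(nbr_w, key=str):
                if c == cu:
                    continue
                gc = gain(c)
                if gc > best_g + GAIN_EPS:
                    best_c, best_g = c, gc
            comm[u] = best_c
            sigma_tot[best_c] += k[u]
            if best_c != cu:
                n_moves += 1
                moved_any = True
        if n_moves == 0:
            return comm, moved_any


def _louvain_assignment(graph: nx.Graph, seed: int, use_weights: bool) -> dict[str, object]:
    """Run full Louvain, returning node → (opaque) community label."""
    rng = random.Random(seed)
    m2 = sum(2.0 * _edge_weight(d, use_weights) for _, _, d in graph.edges(data=True))
    mapping = {u: u for u in graph}
    if m2 == 0:
        return mapping
    h = nx.Graph()
    h.add_nodes_from(graph)
    for u, v, d in graph.edges(data=True):
        h.add_edge(u, v, weight=_edge_weight(d, use_weights))
    while True:
        comm, moved = _one_level(h, m2, rng)
        if not moved:
            return mapping
        mapping = {orig: comm[cur] for orig, cur in mapping.items()}
        agg = nx.Graph()
        agg.add_nodes_from(set(comm.values()))
        for u, v, d in h.edges(data=True):
            cu, cv = comm[u], comm[v]
            w = d["weight"]
            if agg.has_edge(cu, cv):
                agg[cu][cv]["weight"] += w
            else:
                agg.add_edge(cu, cv, weight=w)
        h = agg


def _canonical_ids(graph: nx.Graph, raw: Mapping[str, object]) -> dict[str, str]:
    """Relabel opaque community labels as "1".."k", ordered by smallest member."""
    groups: dict[object, list[str]] = defaultdict(list)
    for node in sorted(graph.nodes):
        groups[raw[node]].append(node)
    ordered = sorted(groups.values(), key=lambda members: members[0])
    out: dict[str, str] = {}
    for i, members in enumerate(ordered, start=1):
        for node in members:
            out[node] = str(i)
    return out


def louvain(net: ProteinNetwork, seed: int = 0, use_weights: bool = False) -> ModulePartition:
    """Louvain community detection; deterministic for a given seed."""
    if net.node_count == 0:
        raise ValueError("empty network")
    if use_weights and not net.is_weighted:
        raise ValueError("use_weights=True on a network lacking weights")
    assignment = _canonical_ids(net.graph, _louvain_assignment(net.graph, seed, use_weights))
    try:
        q = modularity(net, assignment, use_weights)
    except ValueError:  # zero total edge weight
        q = 0.0
    return ModulePartition(
        assignment=assignment, modularity=q, method="louvain", seed=seed,
        params={"use_weights": use_weights},
    )


def incremental_louvain(
    net: ProteinNetwork,
    max_module_size: int,
    seed: int = 0,
    use_weights: bool = False,
) -> ModulePartition:
    """Louvain with recursive subdivision of oversized modules.

    Any module larger than ``max_module_size`` is re-modularized on its
    induced subgraph; recursion stops when every module fits the threshold or
    a module is indivisible (Louvain returns it whole).  Module identifiers
    record the subdivision lineage (``"3.1.2"``).
    """
    if max_module_size < 2:
        raise ValueError("max_module_size must be >= 2")
    if net.node_count == 0:
        raise ValueError("empty network")
    if use_weights and not net.is_weighted:
        raise ValueError("use_weights=True on a network lacking weights")

    final: dict[str, str] = {}

    def subdivide(graph: nx.Graph, prefix: str, depth_seed: int) -> None:
        raw = _louvain_assignment(graph, depth_seed, use_weights)
        ids = _canonical_ids(graph, raw)
        groups: dict[str, list[str]] = defaultdict(list)
        for node, mid in ids.items():
            groups[mid].append(node)
        indivisible = len(groups) == 1
        for mid, members in groups.items():
            full_id = f"{prefix}.{mid}" if prefix else mid
            if len(members) > max_module_size and not indivisible:
                sub = graph.subgraph(members)
                if sub.number_of_edges() == 0:
                    for node in members:
                        final[node] = full_id
                    continue
                subdivide(sub, full_id, depth_seed)
            else:
                for node in members:
                    final[node] = full_id

    subdivide(net.graph, "", seed)
    try:
        q = modularity(net, final, use_weights)
    except ValueError:
        q = 0.0
    return ModulePartition(
        assignment=final, modularity=q, method="incremental_louvain", seed=seed,
        params={"use_weights": use_weights, "max_module_size": max_module_size},
    )


def size_distribution(partition: ModulePartition, threshold: int = 10) -> ModuleSizeDistribution:
    """Module-size histogram; mesoscale modules have size strictly > threshold."""
    sizes = sorted(partition.sizes.values())
    if not sizes:
        raise ValueError("empty partition")
    meso = sum(1 for s in sizes if s > threshold)
    return ModuleSizeDistribution(
        sizes=sizes,
        mesoscale_threshold=threshold,
        mesoscale_count=meso,
        mesoscale_fraction=meso / len(sizes),
    )
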