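"""Protein-protein interaction networks: I/O, combination, descriptive statistics.

A PPIN is an undirected graph over opaque gene identifiers.  Edges may carry a
functional-similarity weight in [0, 1]; a network without weights is *binary*.
Three kinds are distinguished: ``physical`` (direct binding interactions),
``functional`` (co-expression / regulatory links) and ``combined`` (their
inclusive union).
"""

from __future__ import annotations

import json
import logging
import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

NETWORK_KINDS = ("physical", "functional", "combined")


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list lines; carries the 1-based line number."""


@dataclass
class ProteinNetwork:
    """Undirected PPIN over gene identifiers.

    Parameters
    ----------
    graph:
        ``networkx.Graph``; edge weights, when present, live in the ``weight``
        attribute and must lie in [0, 1].
    kind:
        One of ``physical``, ``functional``, ``combined``.
    name:
        Free-text label used in reports.
    """

    graph: nx.Graph
    kind: str = "physical"
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in NETWORK_KINDS:
            raise ValueError(f"unknown network kind {self.kind!r}")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")
        for u, v, d in self.graph.edges(data=True):
            w = d.get("weight")
            if w is not None and not (0.0 <= w <= 1.0):
                raise ValueError(f"edge {u}-{v} weight {w} outside [0, 1]")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    @property
    def is_weighted(self) -> bool:
        """True when every edge carries a weight."""
        if self.edge_count == 0:
            return False
        return all("weight" in d for _, _, d in self.graph.edges(data=True))


@dataclass
class NetworkSummary:
    """Descriptive network properties (degree, paths, density, clustering)."""

    name: str
    kind: str
    weighted: bool
    node_count: int
    edge_count: int
    avg_degree: float
    avg_path_length: float
    diameter: float
    edge_density: float
    clustering_coeff: float
    giant_component_size: int
    path_method: str = "exact"  # "exact" or "sampled:<n_sources>"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_tsv(self) -> str:
        d = asdict(self)
        keys = list(d)
        fmt = lambda v: f"{v:.6g}" if isinstance(v, float) else str(v)
        return "\t".join(keys) + "\n" + "\t".join(fmt(d[k]) for k in keys) + "\n"


def read_edge_list(path: str | Path, kind: str = "physical", name: str | None = None) -> ProteinNetwork:
    """Read a TSV/whitespace edge list: ``gene_a  gene_b  [weight]``.

    ``#`` comment lines are skipped, duplicate pairs (either order) collapse to
    one edge (last weight wins) and self-loops are dropped with a logged count.
    """
    path = Path(path)
    g: nx.Graph = nx.Graph()
    n_loops = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) not in (2, 3):
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            a, b = fields[0], fields[1]
            if a == b:
                n_loops += 1
                continue
            n_lines += 1
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from None
                if not (0.0 <= w <= 1.0):
                    raise EdgeListParseError(f"{path}:{lineno}: weight {w} outside [0, 1]")
                g.add_edge(a, b, weight=w)
            else:
                g.add_edge(a, b)
    if n_lines == 0 and g.number_of_nodes() == 0:
        raise EdgeListParseError(f"{path}: no edges found")
    if n_loops:
        logger.info("%s: dropped %d self-loop(s)", path, n_loops)
    return ProteinNetwork(graph=g, kind=kind, name=name or path.stem)


def write_edge_list(net: ProteinNetwork, path: str | Path) -> None:
    """Write a network as a (weighted) TSV edge list, deterministically sorted."""
    with open(path, "w") as fh:
        for u, v, d in sorted(
            ((min(u, v), max(u, v), d) for u, v, d in net.graph.edges(data=True))
        ):
            if "weight" in d:
                fh.write(f"{u}\t{v}\t{d['weight']:.10g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def combine_networks(a: ProteinNetwork, b: ProteinNetwork, name: str = "combined") -> ProteinNetwork:
    """Inclusive union of two PPIN (node union, unordered-pair edge union).

    When an edge occurs in both inputs with weights, the maximum is kept
    (strongest evidence wins); a weight present on only one side is kept.
    """
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(a.graph.nodes)
    g.add_nodes_from(b.graph.nodes)
    for src in (a.graph, b.graph):
        for u, v, d in src.edges(data=True):
            if g.has_edge(u, v):
                old = g[u][v].get("weight")
                new = d.get("weight")
                if old is not None or new is not None:
                    g[u][v]["weight"] = max(x for x in (old, new) if x is not None)
            else:
                g.add_edge(u, v, **({"weight": d["weight"]} if "weight" in d else {}))
    return ProteinNetwork(graph=g, kind="combined", name=name)


def giant_component(net: ProteinNetwork) -> ProteinNetwork:
    """Induced subgraph on the largest connected component.

    Ties on size are broken toward the component containing the
    lexicographically smallest node.
    """
    if net.node_count == 0:
        raise ValueError("empty network")
    comps = list(nx.connected_components(net.graph))
    maxsize = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == maxsize), key=min)
    return ProteinNetwork(graph=net.graph.subgraph(best).copy(), kind=net.kind, name=net.name)


def _path_stats(
    g: nx.Graph,
    weight: str | None,
    sample_threshold: int,
    n_sample_sources: int,
    seed: int,
) -> tuple[float, float, str]:
    """Average shortest-path length and diameter on a connected graph.

    Exact all-pairs up to ``sample_threshold`` nodes; above that, a seeded
    sample of source nodes is used and the method is recorded.
    """
    n = g.number_of_nodes()
    if n < 2:
        return 0.0, 0.0, "exact"
    nodes = sorted(g.nodes)
    if n <= sample_threshold:
        sources = nodes
        method = "exact"
    else:
        rng = random.Random(seed)
        sources = rng.sample(nodes, min(n_sample_sources, n))
        method = f"sampled:{len(sources)}"
    total = 0.0
    count = 0
    diam = 0.0
    for s in sources:
        if weight is None:
            dist = nx.single_source_shortest_path_length(g, s)
        else:
            dist = nx.single_source_dijkstra_path_length(g, s, weight=weight)
        for t, d in dist.items():
            if t == s:
                continue
            total += d
            count += 1
            if d > diam:
                diam = d
    return total / count, diam, method


def network_summary(
    net: ProteinNetwork,
    weighted: bool = False,
    *,
    path_sample_threshold: int = 2000,
    n_sample_sources: int = 200,
    seed: int = 0,
) -> NetworkSummary:
    """Compute the descriptive properties of a PPIN.

    Binary mode: degree = incident edge count; path lengths are hop counts;
    clustering is the mean local clustering coefficient; density is
    2E / (N(N-1)).

    Weighted mode: degree = node strength (sum of incident weights); shortest
    paths use edge length = weight, i.e. the similarity value itself serves as
    the distance (so path lengths can fall below 1); clustering is the
    geometric-mean local weighted clustering; density uses total edge weight in
    place of the edge count.  Path statistics are computed on the giant
    component.
    """
    if net.node_count == 0:
        raise ValueError("empty network")
    if weighted and not net.is_weighted:
        raise ValueError("weighted summary requested on a network lacking weights")
    g = net.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    wattr = "weight" if weighted else None
    gc_nodes = max(nx.connected_components(g), key=lambda c: (len(c), min(c))) if n else set()
    gc = g.subgraph(gc_nodes)
    apl, diam, method = _path_stats(gc, wattr, path_sample_threshold, n_sample_sources, seed)
    if weighted:
        total_w = sum(d["weight"] for _, _, d in g.edges(data=True))
        avg_degree = 2.0 * total_w / n
        density = 2.0 * total_w / (n * (n - 1)) if n > 1 else 0.0
        clustering = float(sum(nx.clustering(g, weight="weight").values()) / n)
    else:
        avg_degree = 2.0 * e / n
        density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
        clustering = float(nx.average_clustering(g)) if n else 0.0
    return NetworkSummary(
        name=net.name,
        kind=net.kind,
        weighted=weighted,
        node_count=n,
        edge_count=e,
        avg_degree=avg_degree,
        avg_path_length=apl,
        diameter=diam,
        edge_density=density,
        clustering_coeff=clustering,
        giant_component_size=len(gc_nodes),
        path_method=method,
    )


def module_edge_density(net: ProteinNetwork, assignment: Mapping[str, str]) -> dict[str, float]:
    """Per-module internal edge density 2e/(n(n-1)); singleton modules get 0."""
    members: dict[str, set[str]] = {}
    for node, mod in assignment.items():
        members.setdefault(mod, set()).add(node)
    missing = net.nodes - set(assignment)
    if missing:
        raise ValueError(f"assignment does not cover nodes: {sorted(missing)[:5]}")
    out: dict[str, float] = {}
    for mod, nodes in members.items():
        nm = len(nodes)
        if nm < 2:
            out[mod] = 0.0
            continue
        em = net.graph.subgraph(nodes).number_of_edges()
        out[mod] = 2.0 * em / (nm * (nm - 1))
    return out
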