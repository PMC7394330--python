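from __future__ import annotations

import networkx as nx
import pytest

from funcspec import GoDag, ProteinNetwork, SyntheticConfig, generate


def make_net(edges, kind="physical", name="test", weights=None) -> ProteinNetwork:
    g = nx.Graph()
    if weights is None:
        g.add_edges_from(edges)
    else:
        for (u, v), w in zip(edges, weights):
            g.add_edge(u, v, weight=w)
    return ProteinNetwork(graph=g, kind=kind, name=name)


def make_dag(relations, aspects) -> GoDag:
    """relations: iterable of (child, parent, relation); aspects: term → MF/BP/CC."""
    g = nx.DiGraph()
    g.add_nodes_from(aspects)
    for child, parent, rel in relations:
        g.add_edge(child, parent, relation=rel)
    return GoDag(graph=g, aspect=dict(aspects))


@pytest.fixture
def triangle():
    return make_net([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture
def chain_dag():
    """C is_a B is_a A, all molecular function."""
    return make_dag(
        [("C", "B", "is_a"), ("B", "A", "is_a")],
        {"A": "MF", "B": "MF", "C": "MF"},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Planted dataset small enough for per-test reuse (4 blocks of 30, MF only)."""
    cfg = SyntheticConfig(
        n_blocks=4, block_sizes=[30] * 4, dag_depth=2, aspects=("MF",), seed=11
    )
    return generate(cfg)
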