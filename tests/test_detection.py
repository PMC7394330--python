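from __future__ import annotations

import math
import random

import networkx as nx
import pytest

from funcspec import (
    incremental_louvain,
    louvain,
    modularity,
    size_distribution,
)
from helpers import modularity_adjacency
from conftest import make_net


def two_cliques(k: int, bridge: bool = True):
    g = nx.Graph()
    left = [f"a{i}" for i in range(k)]
    right = [f"b{i}" for i in range(k)]
    g.add_edges_from((u, v) for i, u in enumerate(left) for v in left[i + 1:])
    g.add_edges_from((u, v) for i, u in enumerate(right) for v in right[i + 1:])
    if bridge:
        g.add_edge(left[0], right[0])
    return make_net(list(g.edges)), left, right


class TestModularity:
    def test_single_module_is_zero(self, triangle):
        assert modularity(triangle, {n: "m" for n in triangle.nodes}) == pytest.approx(0.0)

    def test_two_disjoint_cliques_half(self):
        net, left, right = two_cliques(3, bridge=False)
        assignment = {**{n: "L" for n in left}, **{n: "R" for n in right}}
        assert modularity(net, assignment) == pytest.approx(0.5)

    def test_barbell_matches_adjacency_oracle(self):
        net, left, right = two_cliques(3, bridge=True)
        assignment = {**{n: "L" for n in left}, **{n: "R" for n in right}}
        assert modularity(net, assignment) == pytest.approx(
            modularity_adjacency(net.graph, assignment), abs=1e-12
        )

    def test_random_graphs_match_oracle_and_networkx(self):
        rng = random.Random(7)
        for _ in range(10):
            g = nx.gnp_random_graph(rng.randint(4, 10), 0.5, seed=rng.randrange(2**31))
            if g.number_of_edges() == 0:
                continue
            net = make_net([(str(u), str(v)) for u, v in g.edges])
            assignment = {n: str(rng.randint(0, 2)) for n in net.nodes}
            q = modularity(net, assignment)
            assert q == pytest.approx(modularity_adjacency(net.graph, assignment), abs=1e-12)
            groups = {}
            for n, c in assignment.items():
                groups.setdefault(c, set()).add(n)
            assert q == pytest.approx(
                nx.community.modularity(net.graph, list(groups.values())), abs=1e-12
            )

    def test_weighted_modularity(self):
        net = make_net([("A", "B"), ("C", "D"), ("B", "C")], weights=[1.0, 1.0, 0.0])
        assignment = {"A": "1", "B": "1", "C": "2", "D": "2"}
        # with the zero-weight bridge contributing nothing, two perfect modules
        assert modularity(net, assignment, use_weights=True) == pytest.approx(0.5)

    def test_missing_node_errors(self, triangle):
        with pytest.raises(ValueError, match="missing"):
            modularity(triangle, {"A": "1", "B": "1"})


class TestLouvain:
    def test_two_disjoint_triangles(self):
        net, left, right = two_cliques(3, bridge=False)
        part = louvain(net, seed=0)
        assert len(part.modules) == 2
        assert part.modularity == pytest.approx(0.5)

    def test_recovers_two_clique_split(self):
        net, left, right = two_cliques(5, bridge=True)
        part = louvain(net, seed=1)
        groups = set(frozenset(m) for m in part.modules.values())
        assert groups == {frozenset(left), frozenset(right)}

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(30, 0.2, seed=5)
        net = make_net([(str(u), str(v)) for u, v in g.edges])
        assert louvain(net, seed=9).assignment == louvain(net, seed=9).assignment

    def test_stored_q_matches_recomputation(self):
        g = nx.gnp_random_graph(25, 0.25, seed=2)
        net = make_net([(str(u), str(v)) for u, v in g.edges])
        part = louvain(net, seed=4)
        assert abs(part.modularity - modularity(net, part.assignment)) < 1e-12

    def test_beats_trivial_partitions(self):
        for seed in range(5):
            g = nx.gnp_random_graph(20, 0.3, seed=seed)
            if g.number_of_edges() == 0:
                continue
            net = make_net([(str(u), str(v)) for u, v in g.edges])
            part = louvain(net, seed=seed)
            q_all_one = modularity(net, {n: "m" for n in net.nodes})
            q_singletons = modularity(net, {n: n for n in net.nodes})
            assert part.modularity >= max(q_all_one, q_singletons) - 1e-12

    def test_constant_weights_match_binary(self):
        g = nx.gnp_random_graph(24, 0.25, seed=3)
        edges = [(str(u), str(v)) for u, v in g.edges]
        binary = make_net(edges)
        for c in (0.2, 1.0):
            weighted = make_net(edges, weights=[c] * len(edges))
            assert louvain(weighted, seed=6, use_weights=True).assignment == \
                louvain(binary, seed=6).assignment

    def test_zero_weight_edges_do_not_bind(self):
        from funcspec import ProteinNetwork

        net, left, right = two_cliques(4, bridge=False)
        g = net.graph
        for u, v in g.edges:
            g[u][v]["weight"] = 1.0
        g.add_edge(left[0], right[0], weight=0.0)
        part = louvain(ProteinNetwork(graph=g, kind="physical"), seed=0, use_weights=True)
        groups = set(frozenset(m) for m in part.modules.values())
        assert groups == {frozenset(left), frozenset(right)}

    def test_planted_partition_recovery(self):
        from helpers import adjusted_rand_index
        from funcspec import SyntheticConfig, simulate_ppin

        aris = []
        for seed in range(20):
            cfg = SyntheticConfig(
                n_blocks=4, block_sizes=[20] * 4, p_in=0.9, p_out=0.05, seed=seed
            )
            net, blocks = simulate_ppin(cfg)
            part = louvain(net, seed=seed)
            genes = sorted(blocks)
            aris.append(adjusted_rand_index(
                [blocks[g] for g in genes], [part.assignment[g] for g in genes]
            ))
        assert sum(aris) / len(aris) >= 0.95

    def test_requires_weights_flag_consistency(self, triangle):
        with pytest.raises(ValueError, match="lacking weights"):
            louvain(triangle, use_weights=True)


class TestIncrementalLouvain:
    def test_noop_when_all_small(self):
        net, *_ = two_cliques(5, bridge=True)
        base = louvain(net, seed=2)
        inc = incremental_louvain(net, max_module_size=6, seed=2)
        assert set(map(frozenset, inc.modules.values())) == set(map(frozenset, base.modules.values()))

    def test_indivisible_triangles_terminate(self):
        net, *_ = two_cliques(3, bridge=False)
        inc = incremental_louvain(net, max_module_size=2, seed=0)
        assert len(inc.modules) == 2
        assert all(len(m) == 3 for m in inc.modules.values())

    def test_subdivides_clique_pairs(self):
        # four 5-cliques in two loosely linked pairs
        g = nx.Graph()
        cliques = []
        for ci in range(4):
            nodes = [f"c{ci}n{i}" for i in range(5)]
            cliques.append(nodes)
            g.add_edges_from((u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:])
        g.add_edge(cliques[0][0], cliques[1][0])
        g.add_edge(cliques[2][0], cliques[3][0])
        g.add_edge(cliques[1][1], cliques[2][1])
        net = make_net(list(g.edges))
        inc = incremental_louvain(net, max_module_size=6, seed=0)
        assert sorted(len(m) for m in inc.modules.values()) == [5, 5, 5, 5]
        assert set(map(frozenset, inc.modules.values())) == set(map(frozenset, cliques))

    def test_size_bound_or_indivisible(self):
        g = nx.gnp_random_graph(60, 0.15, seed=8)
        net = make_net([(str(u), str(v)) for u, v in g.edges])
        inc = incremental_louvain(net, max_module_size=10, seed=8)
        from funcspec import ProteinNetwork

        for mid, members in inc.modules.items():
            if len(members) > 10:
                # oversized modules must be indivisible: Louvain on the induced
                # subgraph returns them whole
                sub = ProteinNetwork(graph=net.graph.subgraph(members).copy(), kind="physical")
                assert len(louvain(sub, seed=8).modules) == 1, mid
        assert abs(inc.modularity - modularity(net, inc.assignment)) < 1e-12

    def test_lineage_ids_recorded(self):
        g = nx.Graph()
        cliques = []
        for ci in range(2):
            nodes = [f"c{ci}n{i}" for i in range(5)]
            cliques.append(nodes)
            g.add_edges_from((u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:])
        g.add_edge(cliques[0][0], cliques[1][0])
        net = make_net(list(g.edges))
        inc = incremental_louvain(net, max_module_size=4, seed=0)
        assert all("." in mid for mid in inc.modules)

    def test_threshold_validation(self, triangle):
        with pytest.raises(ValueError, match="max_module_size"):
            incremental_louvain(triangle, max_module_size=1)


class TestSizeDistribution:
    def test_strictly_greater_than_threshold(self):
        from funcspec.detection import ModulePartition

        assignment = {}
        for i, size in enumerate([2, 2, 11]):
            for j in range(size):
                assignment[f"m{i}n{j}"] = str(i)
        part = ModulePartition(assignment=assignment, modularity=0.0, method="louvain", seed=0)
        dist = size_distribution(part, threshold=10)
        assert dist.sizes == [2, 2, 11]
        assert dist.mesoscale_count == 1

    def test_boundary_size_excluded(self):
        from funcspec.detection import ModulePartition

        assignment = {f"n{j}": "0" for j in range(10)}
        part = ModulePartition(assignment=assignment, modularity=0.0, method="louvain", seed=0)
        assert size_distribution(part, threshold=10).mesoscale_count == 0
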