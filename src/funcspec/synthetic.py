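"""Synthetic benchmark data with planted ground truth.

Emulates the statistical structure the analysis assumes about real proteome
data, without any downloads:

* a modular PPIN drawn from a stochastic block model (planted partition),
* a small rooted ontology DAG per GO aspect (is_a tree plus part_of
  cross-links),
* gene annotations in which each block carries one *signature* leaf term at a
  controlled annotation fraction, over a uniform background annotation rate,
* pathway gene sets aligned with planted blocks.

Every generator is deterministic given the config seed, and writes the same
plain-text formats the real readers consume (TSV edge lists, OBO, two-column
annotation TSV, GMT).

Default parameters are the benchmark's study conditions: 8 blocks of 50
genes, within-block edge probability 0.6 versus 0.02 between blocks,
signature annotation fraction 0.8 over a 5% background rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .network import ProteinNetwork
from .ontology import ASPECTS, AnnotationMap, GoDag
from .validation import PathwayGeneSet


@dataclass
class SyntheticConfig:
    """Parameters of the planted-structure generators (defaults = study conditions)."""

    n_blocks: int = 8
    block_sizes: list[int] = field(default_factory=lambda: [50] * 8)
    p_in: float = 0.6
    p_out: float = 0.02
    signature_fraction: float = 0.8
    background_rate: float = 0.05
    dag_depth: int = 3
    dag_branching: int = 2
    part_of_fraction: float = 0.1
    aspects: tuple[str, ...] = ("MF", "BP", "CC")
    pathway_from_block: int = 0
    off_block_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_sizes) != self.n_blocks:
            raise ValueError("block_sizes length must equal n_blocks")
        if any(s < 1 for s in self.block_sizes):
            raise ValueError("block sizes must be positive")
        for p in (self.p_in, self.p_out, self.signature_fraction,
                  self.background_rate, self.part_of_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.p_in <= self.p_out:
            warnings.warn("p_in <= p_out: planted structure is not recoverable")
        bad = set(self.aspects) - set(ASPECTS)
        if bad:
            raise ValueError(f"unknown aspects {sorted(bad)}")
        if not 0 <= self.pathway_from_block < self.n_blocks:
            raise ValueError("pathway_from_block out of range")


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def gene_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"g{i:04d}" for i in range(sum(cfg.block_sizes))]


def simulate_ppin(cfg: SyntheticConfig) -> tuple[ProteinNetwork, dict[str, int]]:
    """Planted-partition (stochastic block model) network.

    Each within-block node pair is an edge with probability ``p_in``, each
    between-block pair with ``p_out``.  Returns the network and the planted
    gene → block-index assignment.
    """
    rng = _rng(cfg, stage=1)
    genes = gene_ids(cfg)
    blocks: dict[str, int] = {}
    i = 0
    for b, size in enumerate(cfg.block_sizes):
        for _ in range(size):
            blocks[genes[i]] = b
            i += 1
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    bvec = np.array([blocks[g] for g in genes])
    same = bvec[iu] == bvec[ju]
    p = np.where(same, cfg.p_in, cfg.p_out)
    mask = rng.random(len(p)) < p
    g = nx.Graph()
    g.add_nodes_from(genes)
    for a, b_ in zip(iu[mask], ju[mask]):
        g.add_edge(genes[a], genes[b_])
    net = ProteinNetwork(graph=g, kind="physical", name="synthetic")
    return net, blocks


def simulate_ontology(cfg: SyntheticConfig) -> GoDag:
    """Rooted is_a tree of given depth/branching per aspect, plus part_of
    cross-links toward strictly shallower terms (acyclic by construction)."""
    if cfg.dag_depth < 1 or cfg.dag_branching < 1:
        raise ValueError("dag_depth and dag_branching must be >= 1")
    rng = _rng(cfg, stage=2)
    g = nx.DiGraph()
    aspect: dict[str, str] = {}
    for asp in cfg.aspects:
        levels: list[list[str]] = []
        counter = 0

        def new_term() -> str:
            nonlocal counter
            counter += 1
            return f"S{asp}:{counter:04d}"

        root = new_term()
        g.add_node(root)
        aspect[root] = asp
        levels.append([root])
        for depth in range(1, cfg.dag_depth + 1):
            level: list[str] = []
            for parent in levels[-1]:
                for _ in range(cfg.dag_branching):
                    t = new_term()
                    g.add_node(t)
                    aspect[t] = asp
                    g.add_edge(t, parent, relation="is_a")
                    level.append(t)
            levels.append(level)
        # part_of cross-links: deeper term -> strictly shallower non-parent term
        for depth in range(2, cfg.dag_depth + 1):
            for t in levels[depth]:
                if rng.random() < cfg.part_of_fraction:
                    shallow_pool = [
                        s for d in range(depth) for s in levels[d]
                        if not g.has_edge(t, s)
                    ]
                    if shallow_pool:
                        target = shallow_pool[rng.integers(len(shallow_pool))]
                        g.add_edge(t, target, relation="part_of")
    return GoDag(graph=g, aspect=aspect)


def signature_terms(cfg: SyntheticConfig, dag: GoDag) -> dict[str, dict[int, str]]:
    """Per aspect, the reserved signature leaf term of each block (sorted leaves,
    first ``n_blocks`` taken)."""
    out: dict[str, dict[int, str]] = {}
    for asp in cfg.aspects:
        leaves = dag.leaves(asp)
        if len(leaves) < cfg.n_blocks:
            raise ValueError(
                f"aspect {asp}: {len(leaves)} leaves < {cfg.n_blocks} blocks"
            )
        out[asp] = {b: leaves[b] for b in range(cfg.n_blocks)}
    return out


def simulate_annotations(
    cfg: SyntheticConfig, blocks: dict[str, int], dag: GoDag
) -> AnnotationMap:
    """Planted annotations: each gene receives its block's signature term with
    probability ``signature_fraction`` and every other leaf term with
    probability ``background_rate``."""
    rng = _rng(cfg, stage=3)
    sigs = signature_terms(cfg, dag)
    by_aspect: dict[str, dict[str, frozenset[str]]] = {}
    genes = sorted(blocks)
    for asp in cfg.aspects:
        leaves = dag.leaves(asp)
        sig_of_block = sigs[asp]
        m: dict[str, frozenset[str]] = {}
        for gene in genes:
            sig = sig_of_block[blocks[gene]]
            terms: set[str] = set()
            if rng.random() < cfg.signature_fraction:
                terms.add(sig)
            for leaf in leaves:
                if leaf != sig and rng.random() < cfg.background_rate:
                    terms.add(leaf)
            if terms:
                m[gene] = frozenset(terms)
        by_aspect[asp] = m
    return AnnotationMap(by_aspect=by_aspect)


def simulate_pathways(
    cfg: SyntheticConfig,
    blocks: dict[str, int],
    off_block_pool: list[str] | None = None,
) -> list[PathwayGeneSet]:
    """One pathway gene set: the chosen block's genes plus an
    ``off_block_fraction`` of random genes outside the block (drawn from the
    network's other blocks, or from ``off_block_pool`` when given)."""
    rng = _rng(cfg, stage=4)
    b = cfg.pathway_from_block
    members = sorted(g for g, blk in blocks.items() if blk == b)
    pool = off_block_pool if off_block_pool is not None else sorted(
        g for g, blk in blocks.items() if blk != b
    )
    n_off = int(round(cfg.off_block_fraction * len(members)))
    extra: list[str] = []
    if n_off > 0 and pool:
        idx = rng.choice(len(pool), size=min(n_off, len(pool)), replace=False)
        extra = [pool[i] for i in sorted(idx)]
    return [
        PathwayGeneSet(
            name=f"planted_block_{b}",
            genes=frozenset(members) | frozenset(extra),
            source="synthetic planted pathway",
        )
    ]


@dataclass
class SyntheticDataset:
    """Bundle of one synthetic study: network, truth, ontology, annotations, pathways."""

    config: SyntheticConfig
    network: ProteinNetwork
    blocks: dict[str, int]
    dag: GoDag
    annotations: AnnotationMap
    signatures: dict[str, dict[int, str]]
    pathways: list[PathwayGeneSet]


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Run all generators for one config."""
    net, blocks = simulate_ppin(cfg)
    dag = simulate_ontology(cfg)
    ann = simulate_annotations(cfg, blocks, dag)
    return SyntheticDataset(
        config=cfg,
        network=net,
        blocks=blocks,
        dag=dag,
        annotations=ann,
        signatures=signature_terms(cfg, dag),
        pathways=simulate_pathways(cfg, blocks),
    )


def write_ground_truth(ds: SyntheticDataset, path: str | Path) -> None:
    """JSON ground truth: config, block assignment, signature terms, pathway."""
    payload = {
        "config": asdict(ds.config),
        "blocks": ds.blocks,
        "signatures": {a: {str(b): t for b, t in m.items()} for a, m in ds.signatures.items()},
        "pathways": {p.name: sorted(p.genes) for p in ds.pathways},
    }
    payload["config"]["aspects"] = list(ds.config.aspects)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
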