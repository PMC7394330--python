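"""Wang GO semantic similarity and functional edge weighting.

The Wang measure scores a term A by the *semantic contributions* of its
ancestors: S_A(A) = 1, and for any ancestor t,

    S_A(t) = max over children t' of t (within A's ancestor DAG) of w_e · S_A(t')

where w_e is the semantic-contribution factor of the edge relation
(0.8 for ``is_a``, 0.6 for ``part_of`` by Wang's published constants).  The
similarity of two terms is the overlap of their contribution tables:

    sim(A, B) = Σ_{t ∈ T_A ∩ T_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B))

with SV(X) = Σ_t S_X(t).  Gene-level similarity aggregates the pairwise term
similarities of the two genes' annotation sets (best-match-average by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .network import ProteinNetwork
from .ontology import AnnotationMap, GoDag

logger = logging.getLogger(__name__)

#: Wang's published semantic-contribution factors.
W_IS_A = 0.8
W_PART_OF = 0.6

AGGREGATIONS = ("bma", "max", "avg")


@dataclass(frozen=True)
class TermSemanticProfile:
    """S-values of a term over itself and its ancestors, plus their sum SV."""

    term: str
    aspect: str
    svalues: dict[str, float]
    sv_total: float


def term_semantic_profile(
    term: str,
    dag: GoDag,
    w_is_a: float = W_IS_A,
    w_part_of: float = W_PART_OF,
) -> TermSemanticProfile:
    """Compute the Wang semantic profile (S-values) of a term.

    S-values are propagated root-ward through the term's ancestor DAG, each
    edge multiplying by its relation's contribution factor and multiple paths
    resolved by the maximum.
    """
    if term not in dag:
        raise ValueError(f"term {term!r} not in ontology")
    if not (0.0 < w_part_of <= w_is_a < 1.0):
        raise ValueError("require 0 < w_part_of <= w_is_a < 1")
    wmap = {"is_a": w_is_a, "part_of": w_part_of}
    anc = dag.ancestors(term)
    sub = dag.graph.subgraph(anc)
    sval: dict[str, float] = {term: 1.0}
    # child→parent edges: topological order visits children before parents
    for t in nx.topological_sort(sub):
        if t == term:
            continue
        best = 0.0
        for child in sub.predecessors(t):
            if child in sval:
                cand = wmap[sub.edges[child, t]["relation"]] * sval[child]
                if cand > best:
                    best = cand
        sval[t] = best
    return TermSemanticProfile(
        term=term,
        aspect=dag.aspect[term],
        svalues=sval,
        sv_total=sum(sval.values()),
    )


def wang_term_similarity(a: TermSemanticProfile, b: TermSemanticProfile) -> float:
    """Wang similarity of two terms from their semantic profiles, in [0, 1]."""
    if a.aspect != b.aspect:
        raise ValueError(f"aspect mismatch: {a.aspect} vs {b.aspect}")
    common = a.svalues.keys() & b.svalues.keys()
    if not common:
        return 0.0
    num = sum(a.svalues[t] + b.svalues[t] for t in common)
    return num / (a.sv_total + b.sv_total)


class WangSimilarity:
    """Cached Wang term and gene similarity over one DAG and aspect.

    Profiles and pairwise term similarities are memoised, which matters when
    weighting every edge of a large network.
    """

    def __init__(
        self,
        dag: GoDag,
        aspect: str,
        w_is_a: float = W_IS_A,
        w_part_of: float = W_PART_OF,
    ) -> None:
        self.dag = dag
        self.aspect = aspect
        self.w_is_a = w_is_a
        self.w_part_of = w_part_of
        self._profiles: dict[str, TermSemanticProfile] = {}
        self._term_sims: dict[tuple[str, str], float] = {}

    def profile(self, term: str) -> TermSemanticProfile:
        p = self._profiles.get(term)
        if p is None:
            p = term_semantic_profile(term, self.dag, self.w_is_a, self.w_part_of)
            self._profiles[term] = p
        return p

    def term_sim(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        s = self._term_sims.get(key)
        if s is None:
            s = wang_term_similarity(self.profile(t1), self.profile(t2))
            self._term_sims[key] = s
        return s

    def gene_sim(
        self,
        terms1: frozenset[str] | set[str],
        terms2: frozenset[str] | set[str],
        method: str = "bma",
    ) -> float | None:
        """Aggregate term-set similarity; None when either set is empty.

        ``bma``: for each term the best similarity against the other set;
        the two directional averages of those bests are averaged.
        ``max``/``avg``: maximum / mean over all term pairs.
        """
        if not terms1 or not terms2:
            return None
        if method not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {method!r}")
        sims = {(a, b): self.term_sim(a, b) for a in terms1 for b in terms2}
        if method == "max":
            return max(sims.values())
        if method == "avg":
            return sum(sims.values()) / len(sims)
        fwd = sum(max(sims[(a, b)] for b in terms2) for a in terms1) / len(terms1)
        bwd = sum(max(sims[(a, b)] for a in terms1) for b in terms2) / len(terms2)
        return 0.5 * (fwd + bwd)


def gene_similarity(
    g1: str,
    g2: str,
    ann: AnnotationMap,
    dag: GoDag,
    aspect: str,
    method: str = "bma",
    w_is_a: float = W_IS_A,
    w_part_of: float = W_PART_OF,
) -> float | None:
    """Functional similarity of two genes in one GO aspect; None (undefined)
    when either gene carries no annotation in the aspect."""
    engine = WangSimilarity(dag, aspect, w_is_a, w_part_of)
    return engine.gene_sim(ann.terms_for(g1, aspect), ann.terms_for(g2, aspect), method)


def weight_network(
    net: ProteinNetwork,
    ann: AnnotationMap,
    dag: GoDag,
    aspect: str,
    method: str = "bma",
    w_is_a: float = W_IS_A,
    w_part_of: float = W_PART_OF,
) -> ProteinNetwork:
    """Assign Wang gene similarities as edge weights for one GO aspect.

    Node and edge sets are preserved exactly; an edge whose similarity is
    undefined (an unannotated endpoint) receives weight 0.
    """
    engine = WangSimilarity(dag, aspect, w_is_a, w_part_of)
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    n_undef = 0
    for u, v in net.graph.edges:
        s = engine.gene_sim(ann.terms_for(u, aspect), ann.terms_for(v, aspect), method)
        if s is None:
            s = 0.0
            n_undef += 1
        g.add_edge(u, v, weight=s)
    if n_undef:
        logger.info(
            "%s: %d edge(s) with an unannotated endpoint weighted 0 in %s",
            net.name, n_undef, aspect,
        )
    return ProteinNetwork(graph=g, kind=net.kind, name=f"{net.name}-{aspect}")
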