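"""Gene Ontology handling: OBO parsing, annotation maps, ancestor closures.

The ontology is held as a directed acyclic graph of child→parent edges
restricted to ``is_a`` and ``part_of`` relations — the two relation types the
Wang semantic-similarity measure propagates over.  Each term belongs to one of
the three GO aspects: molecular function (MF), biological process (BP),
cellular component (CC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

ASPECTS = ("MF", "BP", "CC")

NAMESPACE_TO_ASPECT = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}

ALLOWED_RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    pass


class AnnotationParseError(ValueError):
    pass


@dataclass
class GoDag:
    """Ontology term DAG with ``is_a``/``part_of`` child→parent relations.

    ``graph`` is a ``networkx.DiGraph`` whose edges point child→parent and
    carry a ``relation`` attribute; ``aspect`` maps each term to MF/BP/CC;
    ``alt_ids`` maps secondary ids to canonical ids.
    """

    graph: nx.DiGraph
    aspect: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"ontology relations contain a cycle: {cycle}")
        bad = {a for a in self.aspect.values()} - set(ASPECTS)
        if bad:
            raise OntologyError(f"unknown aspect(s): {sorted(bad)}")
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def resolve(self, term: str) -> str | None:
        """Canonical id for ``term`` (following alt_id), or None if unknown."""
        if term in self.graph:
            return term
        return self.alt_ids.get(term)

    def parents(self, term: str) -> dict[str, str]:
        """Mapping parent term → relation label."""
        return {p: self.graph.edges[term, p]["relation"] for p in self.graph.successors(term)}

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        """All terms reachable root-ward from ``term`` (cached)."""
        if term not in self.graph:
            raise OntologyError(f"term {term!r} not in ontology")
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term)) | {term}
            self._ancestor_cache[term] = cached
        return cached if include_self else cached - {term}

    def leaves(self, aspect: str | None = None) -> list[str]:
        """Terms with no children, optionally restricted to one aspect, sorted."""
        out = [t for t in self.graph.nodes if self.graph.in_degree(t) == 0]
        if aspect is not None:
            out = [t for t in out if self.aspect[t] == aspect]
        return sorted(out)


def parse_obo(path: str | Path) -> GoDag:
    """Parse an OBO 1.2/1.4 ontology file.

    Obsolete terms are dropped, only ``is_a`` and ``part_of`` relations are
    retained (other relation types are counted and logged), ``alt_id`` entries
    are mapped to their canonical term.  Raises on cycles or unknown
    namespaces.
    """
    multi = obonet.read_obo(str(path), ignore_obsolete=True)
    g = nx.DiGraph()
    aspect: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for term, data in multi.nodes(data=True):
        ns = data.get("namespace")
        if ns is None and len(NAMESPACE_TO_ASPECT) and "default-namespace" in multi.graph:
            ns = multi.graph["default-namespace"][0]
        if ns not in NAMESPACE_TO_ASPECT:
            raise OntologyError(f"term {term}: unknown namespace {ns!r}")
        g.add_node(term)
        aspect[term] = NAMESPACE_TO_ASPECT[ns]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    n_ignored = 0
    for child, parent, rel in multi.edges(keys=True):
        if rel not in ALLOWED_RELATIONS:
            n_ignored += 1
            continue
        if parent in g:
            g.add_edge(child, parent, relation=rel)
    if n_ignored:
        logger.info("%s: ignored %d non-is_a/part_of relation(s)", path, n_ignored)
    return GoDag(graph=g, aspect=aspect, alt_ids=alt_ids)


@dataclass
class AnnotationMap:
    """Per-aspect gene → set-of-terms annotation maps."""

    by_aspect: dict[str, dict[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for asp in self.by_aspect:
            if asp not in ASPECTS:
                raise ValueError(f"unknown aspect {asp!r}")

    def terms_for(self, gene: str, aspect: str) -> frozenset[str]:
        return self.by_aspect.get(aspect, {}).get(gene, frozenset())

    def genes(self, aspect: str | None = None) -> set[str]:
        if aspect is not None:
            return set(self.by_aspect.get(aspect, {}))
        out: set[str] = set()
        for m in self.by_aspect.values():
            out |= set(m)
        return out

    @property
    def aspects(self) -> tuple[str, ...]:
        return tuple(a for a in ASPECTS if self.by_aspect.get(a))


def _is_gaf(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("!"):
                return True
            return len(line.rstrip("\n").split("\t")) >= 15
    return False


def read_annotations(path: str | Path, dag: GoDag) -> AnnotationMap:
    """Read gene→GO annotations from GAF 2.x or a two-column TSV.

    GAF rows with a NOT qualifier are excluded; annotations to unknown or
    obsolete terms are dropped with a logged count; the aspect of each
    annotation is taken from the DAG.
    """
    path = Path(path)
    gaf = _is_gaf(path)
    by_aspect: dict[str, dict[str, set[str]]] = {a: {} for a in ASPECTS}
    n_dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("!", "#")):
                continue
            fields = line.split("\t")
            if gaf:
                if len(fields) < 15:
                    raise AnnotationParseError(f"{path}:{lineno}: GAF row with {len(fields)} columns")
                qualifier = fields[3]
                if "NOT" in qualifier.split("|"):
                    continue
                gene, term = fields[1], fields[4]
            else:
                if len(fields) == 1:
                    fields = line.split()
                if len(fields) != 2:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: expected 2 columns (gene, term), got {len(fields)}"
                    )
                gene, term = fields
            canonical = dag.resolve(term)
            if canonical is None:
                n_dropped += 1
                continue
            asp = dag.aspect[canonical]
            by_aspect[asp].setdefault(gene, set()).add(canonical)
    if n_dropped:
        logger.info("%s: dropped %d annotation(s) to unknown/obsolete terms", path, n_dropped)
    return AnnotationMap(
        by_aspect={
            a: {g: frozenset(ts) for g, ts in m.items()} for a, m in by_aspect.items() if m
        }
    )


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    """Write annotations as a two-column TSV (gene TAB term), sorted."""
    rows = []
    for m in ann.by_aspect.values():
        for gene, terms in m.items():
            rows.extend((gene, t) for t in terms)
    with open(path, "w") as fh:
        for gene, term in sorted(rows):
            fh.write(f"{gene}\t{term}\n")


ASPECT_TO_NAMESPACE = {v: k for k, v in NAMESPACE_TO_ASPECT.items()}


def write_obo(dag: GoDag, path: str | Path, names: Mapping[str, str] | None = None) -> None:
    """Write a GoDag as a minimal OBO 1.2 file (round-trips through parse_obo)."""
    names = names or {}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: funcspec\n")
        for term in sorted(dag.graph.nodes):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {names.get(term, term)}\n")
            fh.write(f"namespace: {ASPECT_TO_NAMESPACE[dag.aspect[term]]}\n")
            for parent, rel in sorted(dag.parents(term).items()):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def propagate_annotations(ann: AnnotationMap, dag: GoDag) -> AnnotationMap:
    """Up-propagate annotations: a gene annotated to a term is annotated to all
    the term's ancestors (the GO true-path rule), per aspect."""
    out: dict[str, dict[str, frozenset[str]]] = {}
    for asp, m in ann.by_aspect.items():
        new: dict[str, frozenset[str]] = {}
        for gene, terms in m.items():
            closure: set[str] = set()
            for t in terms:
                closure |= dag.ancestors(t)
            new[gene] = frozenset(closure)
        out[asp] = new
    return AnnotationMap(by_aspect=out)
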