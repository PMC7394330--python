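"""Hypergeometric functional enrichment of mesoscale modules.

Each GO term annotated to a module's genes is tested for over-representation
with the exact hypergeometric upper tail P[X >= n_f], where the universe
(reference list) holds U genes of which K_term carry the term, and the module
holds N genes of which n_f carry it.  A term is *enriched* when p < alpha
(default 1e-4).  Only mesoscale modules (size strictly greater than the
threshold, 10 by default) are tested; the union of enriched (aspect, term)
pairs over all tested modules is the enriched-function set F.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .detection import ModulePartition
from .ontology import AnnotationMap, GoDag, propagate_annotations

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 1e-4
DEFAULT_MESOSCALE = 10


@dataclass(frozen=True)
class EnrichmentRecord:
    module_id: str
    term: str
    aspect: str
    n_f: int       # module genes annotated to the term
    N: int         # module size
    K_term: int    # universe genes annotated to the term
    U: int         # universe size
    p_value: float
    enriched: bool


@dataclass
class EnrichmentTable:
    """Per-(module, term) enrichment records plus the test's context."""

    records: list[EnrichmentRecord]
    tested_modules: list[str]
    universe_size: int
    alpha: float
    mesoscale_threshold: int

    @property
    def K(self) -> int:
        """Number of tested (mesoscale) modules — the K of heterogeneity."""
        return len(self.tested_modules)

    def to_frame(self) -> pd.DataFrame:
        cols = ["module_id", "term", "aspect", "n_f", "N", "K_term", "U", "p_value", "enriched"]
        return pd.DataFrame([vars(r) for r in self.records], columns=cols)


@dataclass
class EnrichedFunctionSet:
    """The set F of (aspect, term) pairs enriched in >= 1 tested module."""

    modules_by_function: dict[tuple[str, str], list[str]]

    @property
    def F(self) -> set[tuple[str, str]]:
        return set(self.modules_by_function)

    def k_f(self, aspect: str, term: str) -> int:
        return len(self.modules_by_function.get((aspect, term), ()))


def hypergeometric_pvalue(n_f: int, N: int, K_term: int, U: int) -> float:
    """Exact upper-tail hypergeometric probability P[X >= n_f].

    X counts term-annotated genes in a size-N draw from a universe of U genes
    of which K_term are annotated.
    """
    if not (0 <= n_f <= min(N, K_term) and N <= U and K_term <= U):
        raise ValueError(f"inconsistent counts n_f={n_f} N={N} K_term={K_term} U={U}")
    if n_f == 0:
        return 1.0
    return float(hypergeom.sf(n_f - 1, U, K_term, N))


def _term_gene_index(
    ann: AnnotationMap, universe: set[str]
) -> dict[str, dict[str, set[str]]]:
    """aspect → term → universe genes annotated (post-propagation input)."""
    index: dict[str, dict[str, set[str]]] = {}
    for asp, m in ann.by_aspect.items():
        d: dict[str, set[str]] = {}
        for gene, terms in m.items():
            if gene not in universe:
                continue
            for t in terms:
                d.setdefault(t, set()).add(gene)
        index[asp] = d
    return index


def enrich_module(
    module_id: str,
    genes: set[str],
    ann: AnnotationMap,
    dag: GoDag,
    universe: set[str],
    alpha: float = DEFAULT_ALPHA,
    propagate: bool = True,
    min_term_support: int = 2,
) -> list[EnrichmentRecord]:
    """Enrichment records for one module, sorted by ascending p then term id.

    Annotations are up-propagated through the DAG by default (true-path
    rule); terms annotated to fewer than ``min_term_support`` universe genes
    are skipped.
    """
    if not universe:
        raise ValueError("empty universe")
    if not genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    eff = propagate_annotations(ann, dag) if propagate else ann
    index = _term_gene_index(eff, universe)
    return _records_for_module(module_id, genes, index, len(universe), alpha, min_term_support)


def _records_for_module(
    module_id: str,
    genes: set[str],
    index: dict[str, dict[str, set[str]]],
    U: int,
    alpha: float,
    min_term_support: int,
) -> list[EnrichmentRecord]:
    N = len(genes)
    recs: list[EnrichmentRecord] = []
    for asp, terms in index.items():
        for term, annotated in terms.items():
            n_f = len(annotated & genes)
            if n_f == 0:
                continue
            K_term = len(annotated)
            if K_term < min_term_support:
                continue
            p = hypergeometric_pvalue(n_f, N, K_term, U)
            recs.append(
                EnrichmentRecord(
                    module_id=module_id, term=term, aspect=asp,
                    n_f=n_f, N=N, K_term=K_term, U=U,
                    p_value=p, enriched=p < alpha,
                )
            )
    recs.sort(key=lambda r: (r.p_value, r.aspect, r.term))
    return recs


def benjamini_hochberg(records: list[EnrichmentRecord], alpha: float) -> list[EnrichmentRecord]:
    """Re-flag enrichment by BH-adjusted p-values at level ``alpha``."""
    n = len(records)
    if n == 0:
        return records
    order = sorted(range(n), key=lambda i: records[i].p_value)
    adj = [0.0] * n
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = n - rank_from_end
        prev = min(prev, records[i].p_value * n / rank)
        adj[i] = prev
    return [
        EnrichmentRecord(
            module_id=r.module_id, term=r.term, aspect=r.aspect,
            n_f=r.n_f, N=r.N, K_term=r.K_term, U=r.U,
            p_value=r.p_value, enriched=adj[i] < alpha,
        )
        for i, r in enumerate(records)
    ]


def enrich_partition(
    partition: ModulePartition,
    ann: AnnotationMap,
    dag: GoDag,
    universe: set[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    mesoscale_threshold: int = DEFAULT_MESOSCALE,
    propagate: bool = True,
    min_term_support: int = 2,
    correction: str | None = None,
) -> tuple[EnrichmentTable, EnrichedFunctionSet]:
    """Test every mesoscale module of a partition for term enrichment.

    ``universe`` defaults to the partitioned network's node set (the
    self-contained reference); ``correction`` may be ``"bh"`` for
    Benjamini-Hochberg instead of the raw p < alpha threshold.
    """
    if universe is None:
        universe = set(partition.assignment)
    modules = partition.modules
    tested = sorted(m for m, nodes in modules.items() if len(nodes) > mesoscale_threshold)
    eff = propagate_annotations(ann, dag) if propagate else ann
    index = _term_gene_index(eff, universe)
    records: list[EnrichmentRecord] = []
    for mid in tested:
        genes = modules[mid] & universe
        if not genes:
            continue
        recs = _records_for_module(mid, genes, index, len(universe), alpha, min_term_support)
        if correction == "bh":
            recs = benjamini_hochberg(recs, alpha)
        records.extend(recs)
    by_fn: dict[tuple[str, str], list[str]] = {}
    for r in records:
        if r.enriched:
            by_fn.setdefault((r.aspect, r.term), []).append(r.module_id)
    table = EnrichmentTable(
        records=records,
        tested_modules=tested,
        universe_size=len(universe),
        alpha=alpha,
        mesoscale_threshold=mesoscale_threshold,
    )
    return table, EnrichedFunctionSet(modules_by_function=by_fn)
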