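"""Functional homogeneity, heterogeneity and specificity of modules.

For an enriched function f in a module of N genes, n_f of which carry f:

    homogeneity   = n_f / N              (functional coherence inside the module)
    heterogeneity = k_f / K              (f enriched in k_f of the K tested modules)
    specificity   = homogeneity + 1/heterogeneity

Raw specificities are min-max normalized to [0, 1] across all enriched
(module, function) records of one analysis, per aspect.  A module's score is
the best normalized specificity among its enriched functions; modules scoring
strictly above 0.90 are labelled *specific*, the rest *general*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .enrichment import EnrichedFunctionSet, EnrichmentTable

logger = logging.getLogger(__name__)

SPECIFIC_THRESHOLD = 0.90


@dataclass(frozen=True)
class SpecificityRecord:
    module_id: str
    term: str
    aspect: str
    homogeneity: float
    heterogeneity: float
    raw_specificity: float
    normalized_specificity: float


@dataclass(frozen=True)
class ModuleFunctionalProfile:
    module_id: str
    functional_homogeneity: dict[str, float]  # per aspect: H = max homogeneity
    module_specificity: float
    label: str  # "specific" | "general"


def homogeneity(n_f: int, N: int) -> float:
    """Fraction n_f/N of module genes annotated with the function."""
    if N < 1:
        raise ValueError("module size N must be >= 1")
    if not 0 <= n_f <= N:
        raise ValueError(f"require 0 <= n_f <= N, got n_f={n_f}, N={N}")
    return n_f / N


def heterogeneity(k_f: int, K: int) -> float:
    """Fraction k_f/K of tested modules in which the function is enriched."""
    if not 1 <= k_f <= K:
        raise ValueError(f"require 1 <= k_f <= K, got k_f={k_f}, K={K}")
    return k_f / K


def specificity_table(
    table: EnrichmentTable,
    F: EnrichedFunctionSet | None = None,
    K: int | None = None,
) -> list[SpecificityRecord]:
    """Specificity records for every enriched (module, function) pair.

    raw = homogeneity + K/k_f; normalization is min-max per aspect over the
    table's records.  When an aspect has a single record (or all raw scores
    coincide) the normalized value is defined as 1.0 and a warning is logged.
    """
    if K is None:
        K = table.K
    enriched = [r for r in table.records if r.enriched]
    if not enriched:
        return []
    if F is not None:
        k_by_fn = {fn: F.k_f(*fn) for fn in F.F}
    else:
        k_by_fn = {}
        for r in enriched:
            k_by_fn[(r.aspect, r.term)] = k_by_fn.get((r.aspect, r.term), 0) + 1
    raw_recs: list[tuple] = []
    for r in enriched:
        h = homogeneity(r.n_f, r.N)
        k_f = k_by_fn[(r.aspect, r.term)]
        het = heterogeneity(k_f, K)
        raw_recs.append((r, h, het, h + 1.0 / het))
    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    for r, _, _, raw in raw_recs:
        lo[r.aspect] = min(lo.get(r.aspect, raw), raw)
        hi[r.aspect] = max(hi.get(r.aspect, raw), raw)
    out: list[SpecificityRecord] = []
    for r, h, het, raw in raw_recs:
        span = hi[r.aspect] - lo[r.aspect]
        if span == 0.0:
            logger.warning(
                "aspect %s: all raw specificities equal (%.6g); normalized set to 1.0",
                r.aspect, raw,
            )
            norm = 1.0
        else:
            norm = (raw - lo[r.aspect]) / span
        out.append(
            SpecificityRecord(
                module_id=r.module_id, term=r.term, aspect=r.aspect,
                homogeneity=h, heterogeneity=het,
                raw_specificity=raw, normalized_specificity=norm,
            )
        )
    out.sort(key=lambda s: (s.module_id, s.aspect, s.term))
    return out


def module_profiles(
    records: list[SpecificityRecord],
    threshold: float = SPECIFIC_THRESHOLD,
    aggregation: str = "max",
) -> list[ModuleFunctionalProfile]:
    """Per-module functional profiles with the specific/general label.

    A module's specificity is the maximum (or mean, if requested) of its
    records' normalized specificities; the label is *specific* iff the score
    is strictly greater than ``threshold``.  Output is sorted by descending
    score, ties by module id.
    """
    if aggregation not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    by_mod: dict[str, list[SpecificityRecord]] = {}
    for r in records:
        by_mod.setdefault(r.module_id, []).append(r)
    profiles: list[ModuleFunctionalProfile] = []
    for mid, recs in by_mod.items():
        h: dict[str, float] = {}
        for r in recs:
            h[r.aspect] = max(h.get(r.aspect, 0.0), r.homogeneity)
        scores = [r.normalized_specificity for r in recs]
        score = max(scores) if aggregation == "max" else sum(scores) / len(scores)
        profiles.append(
            ModuleFunctionalProfile(
                module_id=mid,
                functional_homogeneity=h,
                module_specificity=score,
                label="specific" if score > threshold else "general",
            )
        )
    profiles.sort(key=lambda p: (-p.module_specificity, p.module_id))
    return profiles


def homogeneity_summary(profiles: list[ModuleFunctionalProfile]) -> pd.DataFrame:
    """Per-aspect max/mean/std (population) of module functional homogeneity H."""
    if not profiles:
        raise ValueError("no profiles to summarize")
    rows = []
    aspects = sorted({a for p in profiles for a in p.functional_homogeneity})
    for asp in aspects:
        vals = pd.Series(
            [p.functional_homogeneity[asp] for p in profiles if asp in p.functional_homogeneity],
            dtype=float,
        )
        rows.append(
            {"aspect": asp, "n_modules": len(vals),
             "max": vals.max(), "mean": vals.mean(), "std": vals.std(ddof=0)}
        )
    return pd.DataFrame(rows, columns=["aspect", "n_modules", "max", "mean", "std"])


def heterogeneity_summary(records: list[SpecificityRecord]) -> pd.DataFrame:
    """Per-aspect min/mean/std (population) of heterogeneity over enriched functions."""
    if not records:
        raise ValueError("no records to summarize")
    rows = []
    aspects = sorted({r.aspect for r in records})
    for asp in aspects:
        per_fn = {(r.aspect, r.term): r.heterogeneity for r in records if r.aspect == asp}
        vals = pd.Series(list(per_fn.values()), dtype=float)
        rows.append(
            {"aspect": asp, "n_functions": len(vals),
             "min": vals.min(), "mean": vals.mean(), "std": vals.std(ddof=0)}
        )
    return pd.DataFrame(rows, columns=["aspect", "n_functions", "min", "mean", "std"])
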