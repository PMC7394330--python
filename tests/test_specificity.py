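from __future__ import annotations

import math

import pytest

from funcspec import (
    heterogeneity,
    heterogeneity_summary,
    homogeneity,
    homogeneity_summary,
    module_profiles,
    specificity_table,
)
from funcspec.enrichment import EnrichmentRecord, EnrichmentTable
from funcspec.specificity import ModuleFunctionalProfile, SpecificityRecord


def make_table(rows, K, aspect="MF"):
    """rows: (module_id, term, n_f, N) for enriched records only."""
    records = [
        EnrichmentRecord(module_id=m, term=t, aspect=aspect, n_f=n_f, N=N,
                         K_term=max(n_f, 1), U=1000, p_value=1e-9, enriched=True)
        for m, t, n_f, N in rows
    ]
    return EnrichmentTable(
        records=records,
        tested_modules=[str(i) for i in range(K)],
        universe_size=1000,
        alpha=1e-4,
        mesoscale_threshold=10,
    )


class TestRatios:
    @pytest.mark.parametrize("n_f,N,expected", [(10, 10, 1.0), (0, 10, 0.0), (8, 10, 0.8)])
    def test_homogeneity(self, n_f, N, expected):
        assert homogeneity(n_f, N) == expected

    def test_homogeneity_errors(self):
        with pytest.raises(ValueError):
            homogeneity(1, 0)
        with pytest.raises(ValueError):
            homogeneity(11, 10)

    @pytest.mark.parametrize("k_f,K,expected", [(1, 50, 0.02), (50, 50, 1.0), (2, 50, 0.04)])
    def test_heterogeneity(self, k_f, K, expected):
        assert heterogeneity(k_f, K) == expected

    def test_heterogeneity_requires_enrichment_somewhere(self):
        with pytest.raises(ValueError):
            heterogeneity(0, 50)


class TestSpecificityTable:
    def test_formula_extremes(self):
        # one function enriched in 1 of K=50 modules with homogeneity 1 -> raw 51;
        # another enriched in all 50 modules with homogeneity 0 -> raw 1
        rows = [("0", "fA", 20, 20)] + [(str(m), "fB", 0, 20) for m in range(50)]
        recs = specificity_table(make_table(rows, K=50))
        by = {(r.module_id, r.term): r for r in recs}
        top = by[("0", "fA")]
        assert top.raw_specificity == pytest.approx(51.0)
        assert top.normalized_specificity == 1.0
        bottom = by[("0", "fB")]
        assert bottom.raw_specificity == pytest.approx(1.0)
        assert bottom.normalized_specificity == 0.0

    def test_min_max_normalization_arithmetic(self):
        # raws engineered to {51, 26, 1}: normalized {1, 0.5, 0}
        rows = [("0", "fA", 20, 20)] + [(str(m), "fB", 20, 20) for m in range(2)] \
            + [(str(m), "fC", 0, 20) for m in range(50)]
        recs = specificity_table(make_table(rows, K=50))
        raws = sorted({round(r.raw_specificity, 9) for r in recs})
        assert raws == [1.0, 26.0, 51.0]
        norm = {round(r.raw_specificity): r.normalized_specificity for r in recs}
        assert norm[51] == 1.0 and norm[26] == pytest.approx(0.5) and norm[1] == 0.0

    def test_raw_monotone_in_k_f_and_homogeneity(self):
        K = 20
        raws_k = []
        for k_f in range(1, K + 1):
            rows = [(str(m), "f", 10, 20) for m in range(k_f)]
            recs = specificity_table(make_table(rows, K=K))
            raws_k.append(recs[0].raw_specificity)
        assert all(a > b for a, b in zip(raws_k, raws_k[1:]))
        raws_h = []
        for n_f in range(0, 21):
            recs = specificity_table(make_table([("0", "f", n_f, 20)], K=K))
            raws_h.append(recs[0].raw_specificity)
        assert all(a < b for a, b in zip(raws_h, raws_h[1:]))

    def test_single_function_ranking_equals_homogeneity_ranking(self):
        # every function enriched in exactly one module: 1/heterogeneity constant
        rows = [(str(m), f"f{m}", m + 5, 20) for m in range(5)]
        recs = specificity_table(make_table(rows, K=5))
        by_spec = sorted(recs, key=lambda r: -r.normalized_specificity)
        by_hom = sorted(recs, key=lambda r: -r.homogeneity)
        assert [r.module_id for r in by_spec] == [r.module_id for r in by_hom]

    def test_single_record_normalizes_to_one_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="funcspec.specificity"):
            recs = specificity_table(make_table([("0", "f", 10, 20)], K=5))
        assert recs[0].normalized_specificity == 1.0
        assert any("normalized" in m for m in caplog.messages)

    def test_empty_table_empty_output(self):
        assert specificity_table(make_table([], K=5)) == []

    def test_normalization_per_aspect(self):
        t = make_table([("0", "fA", 20, 20), ("1", "fB", 10, 20)], K=4)
        t.records += make_table([("0", "gA", 5, 20), ("1", "gB", 15, 20)], K=4, aspect="BP").records
        recs = specificity_table(t)
        for asp in ("MF", "BP"):
            norms = [r.normalized_specificity for r in recs if r.aspect == asp]
            assert max(norms) == 1.0 and min(norms) == 0.0


class TestModuleProfiles:
    def _recs(self, scores):
        return [
            SpecificityRecord(module_id=m, term=f"f{m}", aspect="MF", homogeneity=0.5,
                              heterogeneity=0.2, raw_specificity=5.0, normalized_specificity=s)
            for m, s in scores.items()
        ]

    def test_strict_threshold(self):
        profiles = module_profiles(self._recs({"a": 1.0, "b": 0.90, "c": 0.95}))
        labels = {p.module_id: p.label for p in profiles}
        assert labels == {"a": "specific", "b": "general", "c": "specific"}

    def test_sorted_by_score_then_id(self):
        profiles = module_profiles(self._recs({"b": 0.40, "a": 0.95, "c": 0.40}))
        assert [p.module_id for p in profiles] == ["a", "b", "c"]

    def test_max_aggregation_over_functions(self):
        recs = self._recs({"m": 0.2}) + self._recs({"m": 0.99})
        p = module_profiles(recs)[0]
        assert p.module_specificity == 0.99 and p.label == "specific"

    def test_mean_aggregation_option(self):
        recs = self._recs({"m": 0.2}) + self._recs({"m": 0.8})
        p = module_profiles(recs, aggregation="mean")[0]
        assert p.module_specificity == pytest.approx(0.5)

    def test_H_is_max_homogeneity_per_aspect(self):
        recs = [
            SpecificityRecord("m", "f1", "MF", 0.3, 0.5, 2.3, 0.5),
            SpecificityRecord("m", "f2", "MF", 0.9, 0.5, 2.9, 0.6),
            SpecificityRecord("m", "f3", "BP", 0.4, 0.5, 2.4, 0.2),
        ]
        p = module_profiles(recs)[0]
        assert p.functional_homogeneity == {"MF": 0.9, "BP": 0.4}


class TestSummaries:
    def _profile(self, mid, h):
        return ModuleFunctionalProfile(module_id=mid, functional_homogeneity={"MF": h},
                                       module_specificity=0.5, label="general")

    def test_single_module(self):
        df = homogeneity_summary([self._profile("m", 0.8)])
        row = df.iloc[0]
        assert row["max"] == row["mean"] == 0.8 and row["std"] == 0.0

    def test_two_values_population_std(self):
        df = homogeneity_summary([self._profile("a", 0.6), self._profile("b", 1.0)])
        row = df.iloc[0]
        assert row["max"] == 1.0
        assert row["mean"] == pytest.approx(0.8)
        assert row["std"] == pytest.approx(0.2)

    def test_heterogeneity_summary_per_function(self):
        recs = [
            SpecificityRecord("a", "f1", "MF", 0.5, 0.1, 10.5, 0.9),
            SpecificityRecord("b", "f1", "MF", 0.5, 0.1, 10.5, 0.9),
            SpecificityRecord("a", "f2", "MF", 0.5, 0.3, 3.8, 0.1),
        ]
        df = heterogeneity_summary(recs)
        row = df.iloc[0]
        # two distinct functions: heterogeneities {0.1, 0.3}
        assert row["n_functions"] == 2
        assert row["min"] == pytest.approx(0.1)
        assert row["mean"] == pytest.approx(0.2)

    def test_planted_mean_homogeneity_recovers_signature_fraction(self, small_dataset):
        from funcspec import enrich_partition, louvain

        ds = small_dataset
        part = louvain(ds.network, seed=3)
        table, fset = enrich_partition(part, ds.annotations, ds.dag)
        profiles = module_profiles(specificity_table(table, fset))
        df = homogeneity_summary(profiles)
        mean_h = df[df["aspect"] == "MF"]["mean"].iloc[0]
        assert abs(mean_h - ds.config.signature_fraction) <= 0.07
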