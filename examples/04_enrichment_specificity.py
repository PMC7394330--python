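"""Hypergeometric enrichment and functional specificity scoring.

Runs the full planted study: each block of the synthetic network carries one
signature GO term in 80% of its genes over a 5% background. Enrichment finds
the signatures; the specificity score (homogeneity + 1/heterogeneity,
min-max normalized) separates specific from general modules.
"""

from funcspec import (
    SyntheticConfig, enrich_partition, generate, louvain, module_profiles,
    specificity_table,
)

ds = generate(SyntheticConfig(aspects=("MF",), seed=1))
part = louvain(ds.network, seed=1)

table, fset = enrich_partition(part, ds.annotations, ds.dag)
print(f"tested modules K = {table.K}, enriched functions |F| = {len(fset.F)}")

recs = specificity_table(table, fset)
top = sorted(recs, key=lambda r: -r.normalized_specificity)[:3]
print("\ntop specificity records (module, term, homogeneity, heterogeneity, norm):")
for r in top:
    print(f"  {r.module_id:>2s}  {r.term}  h={r.homogeneity:.2f} "
          f"het={r.heterogeneity:.3f}  spec={r.normalized_specificity:.3f}")

profiles = module_profiles(recs)
for p in profiles:
    print(f"module {p.module_id}: H_MF={p.functional_homogeneity['MF']:.2f} "
          f"specificity={p.module_specificity:.3f} -> {p.label}")

print("\nHomogeneity near 0.8 recovers the planted 80% signature fraction; a")
print("signature enriched in exactly one of K modules has heterogeneity 1/K, so")
print("its module scores near the table maximum and is labelled specific (>0.90).")
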