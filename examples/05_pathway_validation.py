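"""Pathway-overlap validation of specific vs general modules.

Checks that the genes of a known pathway (here: a planted gene set aligned
with one network block) concentrate in modules labelled specific rather than
general.
"""

from funcspec import (
    SyntheticConfig, enrich_partition, generate, louvain, module_profiles,
    overlap_table, specificity_table,
)

ds = generate(SyntheticConfig(aspects=("MF",), seed=1))
part = louvain(ds.network, seed=1)
table, fset = enrich_partition(part, ds.annotations, ds.dag)
profiles = module_profiles(specificity_table(table, fset))

df = overlap_table(ds.pathways, profiles, part, ds.network)
print(df.to_string(index=False))

print("\nspecific_fraction is the share of the pathway's in-network genes that")
print("fall in specific modules; genes of unscored (sub-mesoscale) modules count")
print("in neither fraction. A high specific_fraction validates that specificity")
print("ranking concentrates biologically coherent gene sets.")
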