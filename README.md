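# funcspec

Functional homogeneity and specificity of topological modules in
protein–protein interaction networks (PPIN).

## The problem

Community detection on a PPIN yields *topological* modules — densely
interconnected groups of proteins. Whether those groups are *functional*
modules is usually judged by GO-term enrichment alone, which says nothing
about how coherent a module is internally or how exclusively a function maps
to it. `funcspec` is a library for systems biologists who want to quantify
exactly that, for physical (direct binding), functional (co-expression /
regulatory) and combined interaction networks, binary or weighted by gene
functional similarity.

## The method

1. **Module detection.** Louvain maximization of modularity
   *Q* = Σ<sub>i</sub> (e<sub>ii</sub> − a<sub>i</sub>²), where e<sub>ii</sub>
   is the fraction of edge weight inside module *i* and a<sub>i</sub> the
   fraction of edge endpoints attached to it. An *incremental* variant
   recursively re-modularizes modules above a size threshold, mitigating the
   resolution limit; sub-modules keep lineage identifiers (`3.1.2`).
2. **Edge weighting (optional).** Wang semantic similarity over the GO DAG
   (semantic contributions 0.8 per `is_a`, 0.6 per `part_of` edge),
   aggregated gene-to-gene by best-match-average, assigned as edge weights
   per GO aspect (MF/BP/CC).
3. **Enrichment.** Each mesoscale module (size strictly > 10) is tested per
   GO term with the exact hypergeometric upper tail; terms with
   *p* < 10⁻⁴ are enriched. The union over modules is the enriched-function
   set *F*.
4. **Specificity.** For an enriched function *f* in a module of *N* genes,
   *n<sub>f</sub>* annotated, enriched in *k<sub>f</sub>* of *K* tested
   modules:

   - homogeneity = n<sub>f</sub>/N
   - heterogeneity = k<sub>f</sub>/K
   - **specificity = homogeneity + 1/heterogeneity**, min–max normalized to
     [0, 1] per aspect.

   A module's score is its best normalized record; scores strictly > 0.90
   label the module **specific**, otherwise **general**.
5. **Validation.** The genes of known pathway sets (GMT) are intersected with
   the network and split by the label of their module; a high specific
   fraction validates the ranking.

A planted-truth generator (stochastic block model network, synthetic GO DAG,
signature-term annotations, block-aligned pathways) makes every stage
testable end to end without downloads.

## Worked example

```python
from funcspec import (SyntheticConfig, generate, louvain, enrich_partition,
                      specificity_table, module_profiles)

ds = generate(SyntheticConfig(aspects=("MF",), seed=1))   # 8 blocks x 50 genes
part = louvain(ds.network, seed=1)
table, fset = enrich_partition(part, ds.annotations, ds.dag)
profiles = module_profiles(specificity_table(table, fset))
```

This prints, via `examples/04_enrichment_specificity.py`:

```
tested modules K = 8, enriched functions |F| = 14
module 8: H_MF=0.88 specificity=1.000 -> specific
module 4: H_MF=0.86 specificity=0.993 -> specific
...
```

The detection step (`examples/03_module_detection.py`) reports
`Q = 0.6817, modules = 8, sizes = [50, 50, 50, 50, 50, 50, 50, 50]` — the
eight planted blocks recovered exactly. Module homogeneities cluster around
0.8 because 80% of each block's genes carry its signature term; each
signature is enriched in exactly one of the K = 8 modules (heterogeneity
1/8), so every planted module scores near the table maximum and is labelled
specific. The planted pathway's genes land 100% in specific modules
(`examples/05_pathway_validation.py`).

The `examples/` scripts walk through each capability; a thin CLI
(`funcspec build|weight|detect|enrich|specificity|validate|simulate|run`)
wraps the same functions for shell use, driven by a YAML config with an
explicit seed, and writes a manifest making every run byte-reproducible.

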