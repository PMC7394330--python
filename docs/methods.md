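# Methods

## Networks and their descriptive statistics

A PPIN is an undirected simple graph over opaque, case-sensitive gene
identifiers (no identifier mapping is performed; inputs are assumed
pre-mapped to one namespace). Self-loops are dropped at parse time and
duplicate pairs collapse. Three kinds are tracked — physical, functional,
combined — with *combined* defined as the inclusive union of node and edge
sets. When the same edge carries weights in both inputs, the maximum is
kept: the strongest available evidence for the interaction wins.

Binary summaries use hop-count shortest paths, mean local clustering and
density 2E/(N(N−1)). Weighted summaries use node strength for degree and —
deliberately and unconventionally — **edge length = weight** for shortest
paths, so a path across high-similarity edges is *longer* than one across
low-similarity edges and average path lengths can fall below 1. This
convention is exposed in the summary (`weighted` flag) rather than hidden,
because similarity weights admit both readings (similarity-as-distance vs
similarity-as-conductance) and the package's weighted path statistics are
only comparable under a stated convention. Weighted clustering is the
geometric-mean (Onnela) local coefficient as implemented by networkx;
weighted density substitutes total edge weight for the edge count. Path
statistics are computed on the giant component; above a configurable node
count (default 2000) an exact all-pairs sweep is replaced by a seeded sample
of source nodes and the summary records which method was used.

## Wang semantic similarity

Term profiles follow the Wang recursion: S_A(A) = 1 and, walking root-ward
through A's ancestor DAG, S_A(t) = max over children t′ of t of
w_e · S_A(t′), with contribution factors w_is_a = 0.8 and w_part_of = 0.6
(Wang's published constants; configurable, with the constraint
0 < w_part_of ≤ w_is_a < 1). Only `is_a` and `part_of` relations propagate;
all other relation types are dropped at OBO parse time with a logged count.
Term similarity is the shared-ancestor contribution ratio
Σ(S_A + S_B) / (SV(A) + SV(B)).

Gene-level aggregation defaults to best-match-average in the symmetric
two-direction form: the mean of (average of forward bests) and (average of
backward bests). `max` and `avg` over all term pairs are options. Genes are
compared on their *direct* annotations (no up-propagation before
similarity): the Wang profile already encodes ancestry, and propagating
first would inflate every similarity toward 1. An edge with an unannotated
endpoint receives weight 0 rather than being removed, so weighting never
changes node or edge counts and binary/weighted analyses stay directly
comparable.

## Module detection

Modularity is computed in the diagonal form Q = Σ_i (e_ii − a_i²) over
module indices, equivalent to the adjacency-matrix definition (the test
suite asserts the equivalence against a brute-force oracle). Louvain is
implemented in-package as the standard two-phase algorithm: repeated sweeps
of local node moves to the neighboring community with maximal modularity
gain, then aggregation of communities into super-nodes, iterated until no
gain remains. Determinism and tie-breaking are pinned down precisely because
they affect reproducibility: node visit order is shuffled by a seeded RNG
recorded in the partition; gains ≤ 1e−12 count as zero; ties on gain go to
the smallest community identifier; final module ids are assigned "1".."k"
ordered by each module's lexicographically smallest member. Edges of weight
0 contribute nothing to any gain, so a zero-weight edge can never hold two
communities together. The resolution parameter is fixed at 1.

Incremental Louvain re-runs Louvain on the induced subgraph of every module
larger than `max_module_size`, replacing it by its sub-modules, recursing
until all modules fit or a module is indivisible (Louvain returns it whole).
Identifiers record lineage (`3.1.2`) and the final Q is recomputed on the
full network. The size threshold is a required parameter with no silent
default; 200 is a reasonable starting point for proteome-scale networks,
where most informative modules fall in the 10–200 range. Termination is
guaranteed: every subdivision strictly shrinks the subproblem or stops as
indivisible.

Mesoscale modules are those with size **strictly greater than 10**; smaller
modules (most of them isolated pairs in sparse interactomes) are reported in
the size distribution but never tested for enrichment.

## Enrichment

Per mesoscale module and term, the exact hypergeometric upper tail
P[X ≥ n_f] is computed (scipy), with the universe U defaulting to the
analyzed network's node set — a self-contained choice recorded in the
manifest; an external reference list can be supplied instead. Annotations
are up-propagated through the DAG (true-path rule) before counting, so a
gene annotated to a leaf supports all its ancestors; propagation is
configurable. Terms annotated to fewer than 2 universe genes are skipped
(their p-values are degenerate). The enrichment flag uses the raw threshold
p < 1e−4 (strict); Benjamini–Hochberg adjustment is available as an option
but not the default. Records are sorted by ascending p, ties by term id,
for stable output.

## Specificity

For each enriched (module, function) record: homogeneity n_f/N,
heterogeneity k_f/K, raw specificity = homogeneity + K/k_f. **K is the
number of tested (mesoscale) modules**, not the total module count: k_f can
only count tested modules, so this keeps k_f ≤ K an invariant; K is recorded
in the manifest. Raw scores are min–max normalized per aspect across all
records of one analysis; cross-network comparisons should use raw scores.
When an aspect yields a single record (or all raws coincide) min–max is
undefined; the normalized value is set to 1.0 with a logged warning.

A module's functional homogeneity H per aspect is the maximum homogeneity
among its enriched functions (the "maximally enriched function" read as
max-homogeneity; a min-p-value variant would be a one-line change and is
deliberately not the default). The module-level specificity score is the
maximum of its records' normalized specificities — a module is as specific
as its most specific function — with mean available as an option. Labels use
a strict threshold: specific ⇔ score > 0.90. Summary tables report max /
mean / population-std of H per aspect, and min / mean / population-std of
heterogeneity per enriched function.

## Pathway validation

Pathway gene sets (GMT) are intersected with the network node set; the
denominator of both fractions is |pathway ∩ network|. Genes falling in
modules that were never scored (sub-mesoscale) are counted in neither
fraction and reported as `n_unlabeled`, so specific + general ≤ 1 with
equality exactly when every in-network pathway gene sits in a profiled
module. An empty intersection yields missing fractions plus a warning rather
than zeros, to keep "no evidence" distinct from "contradicting evidence".

## Synthetic benchmark

The generator emulates the statistical structure the analysis assumes:

* **Network**: planted-partition stochastic block model. Defaults — 8 blocks
  of 50 genes, p_in = 0.6, p_out = 0.02 — give dense, unambiguous modules at
  a size comfortably above the mesoscale cut while keeping a full
  20-replicate study under a minute on one core.
* **Ontology**: per aspect, a rooted is_a tree of depth 3 and branching 2
  (8 leaves — one signature leaf per block) plus a 10% rate of part_of
  cross-links to shallower terms, acyclic by construction.
* **Annotations**: each gene carries its block's signature leaf with
  probability 0.8 and every other leaf with probability 0.05. Signatures are
  leaves so up-propagation creates realistic shared-ancestor enrichment
  without colliding signatures.
* **Pathways**: one gene set equal to a chosen block plus a 10% fraction of
  off-block genes, emulating the partial pathway–network overlap seen with
  curated sets.

All generators are deterministic given the config seed (per-stage
`numpy` generators seeded as `[seed, stage]`), and write the same plain-text
formats the parsers read, so fixtures exercise the real I/O paths.

What the generator does **not** emulate: scale-free degree structure, hub
proteins, annotation depth heterogeneity, inter-aspect annotation
correlation, or curation bias. Passing the planted-recovery tests therefore
shows the pipeline's inferential machinery is correct under clean modular
structure — it does not certify performance on real interactomes, where
module boundaries are far fuzzier and annotations sparser.

## Numerical and degenerate-input choices

* Modularity recomputed from a stored assignment must match the stored Q to
  1e−12; modularity on a zero-total-weight network is an error (Louvain
  returns singletons with Q = 0 in that case).
* Hypergeometric p-values are exact (scipy's `hypergeom.sf`), verified
  against big-integer combinatorial summation to 1e−10 relative error.
* Wang profile computation is dynamic programming in topological order,
  verified against exhaustive path enumeration on small DAGs.
* TSV floats are written with `%.10g`; JSON with sorted keys — byte-stable
  output is a design requirement, and the manifest's timestamp is optional
  (absent by default) for exactly that reason.
* Benchmarks for the exhaustive Louvain-optimality check use sparse random
  graphs (G(n, 0.25), n ≤ 8): interactomes are sparse, and dense
  unstructured graphs contain instances where no single greedy run can reach
  the global optimum, which would measure the instance distribution rather
  than the implementation.

## Known limitations

* Single-membership modules only; overlapping or hierarchical communities
  beyond the incremental lineage are out of scope.
* Only the Wang measure is implemented (no Resnik/Lin/SimRel information-
  content measures).
* The raw p < 1e−4 threshold, used for comparability, is anti-conservative
  under heavy multiple testing; BH is available but changes |F|.
* Heterogeneity depends on K, so specificity values are not comparable
  between analyses with different numbers of tested modules except via raw
  scores.
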