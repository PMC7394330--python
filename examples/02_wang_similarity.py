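"""Wang GO semantic similarity between terms and genes.

Builds the three-term chain ontology C is_a B is_a A and shows the S-value
recursion, the term-level Wang similarity, and the best-match-average
gene-level similarity used to weight network edges.
"""

import networkx as nx

from funcspec import (
    AnnotationMap, GoDag, gene_similarity, term_semantic_profile, wang_term_similarity,
)

g = nx.DiGraph()
g.add_edge("C", "B", relation="is_a")
g.add_edge("B", "A", relation="is_a")
dag = GoDag(graph=g, aspect={"A": "MF", "B": "MF", "C": "MF"})

pc = term_semantic_profile("C", dag)
pb = term_semantic_profile("B", dag)
print("S-values of C (w_is_a = 0.8):", {t: round(v, 3) for t, v in pc.svalues.items()})
print(f"SV(C) = {pc.sv_total:.2f}, SV(B) = {pb.sv_total:.2f}")
print(f"sim(C, B) = {wang_term_similarity(pc, pb):.4f}   # = 3.24/4.24")

ann = AnnotationMap(by_aspect={"MF": {"g1": frozenset({"C"}), "g2": frozenset({"B", "C"})}})
s = gene_similarity("g1", "g2", ann, dag, "MF")
print(f"gene similarity g1~g2 (best-match-average) = {s:.4f}")

print("\nEach ancestor contributes a geometrically decaying S-value; two terms")
print("are similar in proportion to the shared part of those contributions.")
print("The gene score aggregates the best term matches in both directions and")
print("becomes the edge weight of the corresponding protein interaction.")
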