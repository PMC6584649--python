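"""GO semantic similarity and association scores on a toy ontology.

Information content is estimated from an annotation corpus, term pairs
are compared by Lin similarity, protein pairs by FunSim (the mean over
all cross term pairs), and term-pair association by a PMI-style
log-odds over co-occurrence events.
"""

import networkx as nx

from phytoppi.go_semantics import (
    GoDag, build_association_table, build_ic, funsim, pair_association,
    term_similarity,
)

# C -> A, D -> A, D -> B, A -> R, B -> R  (child -> parent)
g = nx.DiGraph([("C", "A"), ("D", "A"), ("D", "B"), ("A", "R"), ("B", "R")])
dag = GoDag(g, aspect_of={t: "CC" for t in g})
corpus = {
    "p1": {"C"}, "p2": {"C"}, "p3": {"D"}, "p4": {"D"},
    "p5": {"A"}, "p6": {"B"}, "p7": {"B"}, "p8": {"R"},
}
build_ic(dag, corpus)
print("information content:", {t: round(ic, 3) for t, ic in sorted(dag.ic.items())})
# root R annotates everything -> IC 0; rare leaves C, D are most informative

print(f"Lin(C, D) = {term_similarity('C', 'D', dag):.3f}  (share ancestor A)")
print(f"Lin(C, B) = {term_similarity('C', 'B', dag):.3f}  (only share the root)")
print(f"FunSim({{C,A}}, {{D}}) = {funsim({'C', 'A'}, {'D'}, dag):.3f}")

events = [{"C", "D"}, {"C", "D"}, {"A"}, {"B"}]
table = build_association_table("IAS", events)
print(f"\nIAS(C, D) over 4 events = {table.get('C', 'D'):.3f}")
print(f"pair IAS of ({{C}}, {{D,B}}) = {pair_association({'C'}, {'D', 'B'}, table):.3f}")
# positive log-odds: C and D co-occur more often than independence predicts
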