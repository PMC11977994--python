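"""Combined Lin-Resnik similarity on a toy four-term ontology.

Builds the minimal DAG R <- {A, B}, A <- C with one annotation per term
and prints the information content and pairwise similarities.
"""

from sefx import (
    AnnotationCorpus,
    Ontology,
    information_content,
    pairwise_similarity,
)

onto = Ontology([("C", "A"), ("A", "R"), ("B", "R")], top_level=["A", "B"])
corpus = AnnotationCorpus({"R": 1, "A": 1, "B": 1, "C": 1})

ic = information_content(onto, corpus, smooth=False)
print("information content (-ln p, cumulative annotation probability):")
for term in onto.terms:
    print(f"  IC({term}) = {ic[term]:.4f}")

sim = pairwise_similarity(onto, corpus, smooth=False)
print(f"\nzero-intercept Lin-on-Resnik multiplier m = {sim.multiplier:.4f}")
print("combined similarity (mean of Lin and capped m*Resnik):")
for a in onto.terms:
    row = "  ".join(f"{sim.sim(a, b):.3f}" for b in onto.terms)
    print(f"  {a}: {row}")
print(
    "\nC is most similar to itself (1.0) and to its parent A; A and B share"
    "\nonly the root (IC 0), so their similarity is driven to 0."
)
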