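"""Mutation scores and the pairwise mutation-impact function on a toy matrix.

Three genes, three patients. Patient burdens are N = (2, 2, 0): a mutation in
a two-mutation patient contributes 1/2 to its gene's score, and a patient
with no mutations contributes nothing. The unmutated patient shows why the
background score exists: any gene with no mutation at all would receive
1/N_max. The MIF then couples two scores through the squared distance between
their incidence rows — identical profiles attract maximally.
"""

import numpy as np

from menc import (MutationMatrix, compute_mif, compute_mutation_scores,
                  gene_distance)

m = MutationMatrix(
    genes=["g1", "g2", "g3"],
    patients=["p1", "p2", "p3"],
    values=np.array([[1, 1, 0],
                     [0, 1, 0],
                     [1, 0, 0]]),
)
scores = compute_mutation_scores(m)

print("patient burdens N_k:", m.patient_burdens().tolist())
for g in m.genes:
    print(f"M({g}) = {scores.get(g):.3f}")
print(f"background score (1/N_max) = {scores.bms:.3f}\n")

for i, j in (("g1", "g2"), ("g1", "g3"), ("g2", "g3")):
    d = gene_distance(m.row(i), m.row(j))
    mif = compute_mif(scores, m, i, j)
    print(f"dist({i},{j}) = {d:.3f}   MIF({i},{j}) = {mif:.3f}")
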