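"""Percent-identity matrix and neighbour-joining dendrogram for the four
bundled nisin cores (A, Z, E, U).

Distances are 100 - identity; the tree pairs the lactococcal variants
(A, Z) against the streptococcal ones (E, U).
"""

from lantipipe import CORE_PEPTIDES, PeptideRecord, identity_matrix, nj_tree

peptides = [
    PeptideRecord(label, seq, variant_name=f"nisin {label}")
    for label, seq in CORE_PEPTIDES.items()
]
matrix = identity_matrix(peptides)
print("percent identity matrix:")
print(matrix.to_frame().round(1).to_string())

newick = nj_tree(matrix)
print("\nneighbour-joining tree (branch lengths in identity-distance units):")
print(newick)
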