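"""Compare the nisin A and nisin E gene-cluster layouts and classify gene
content.

The nisin E operon keeps all eleven canonical genes but rearranges them
(structural gene between the FEG transporter and PRK regulatory genes);
adjacency comparison quantifies that as synteny breakpoints.  Genomes
carrying only RKFEG are the immunity/sensing pattern seen across the
producer species' pangenome.
"""

from lantipipe import classify_cluster, compare_layouts
from lantipipe.refdata import NISIN_A_LAYOUT, NISIN_E_LAYOUT

print(f"nisin A layout: {NISIN_A_LAYOUT}")
print(f"nisin E layout: {NISIN_E_LAYOUT}")

comparison = compare_layouts(NISIN_A_LAYOUT, NISIN_E_LAYOUT)
print(
    f"shared gene adjacencies: {comparison['shared_adjacencies']}/10, "
    f"breakpoints: {comparison['breakpoints']}"
)

for roles in ("ABTCIPRKFEG", "RKFEG", "RKFE", ""):
    category = classify_cluster(set(roles)).category
    print(f"roles {{{roles or 'none'}}} -> {category}")
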