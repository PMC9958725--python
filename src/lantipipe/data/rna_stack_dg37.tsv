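# RNA nearest-neighbour stack free energies at 37 C (kcal/mol).
# Key: top and bottom strands of the two stacked pairs, BOTH written
# 5'->3' (outer pair first on top), e.g. GC/GC is 5'GC3' over 3'CG5'.
# Watson-Crick only; stacks involving a G:U wobble pair are assigned
# a uniform -0.5 at evaluation time (documented simplification).
AA/UU	-0.93
AC/GU	-2.24
AG/CU	-2.08
AU/AU	-1.10
CA/UG	-2.11
CC/GG	-3.26
CG/CG	-2.36
CU/AG	-2.08
GA/UC	-2.35
GC/GC	-3.42
GG/CC	-3.26
GU/AC	-2.24
UA/UA	-1.33
UC/GA	-2.35
UG/CA	-2.11
UU/AA	-0.93
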