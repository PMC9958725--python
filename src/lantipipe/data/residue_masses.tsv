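# Amino acid residue masses in Daltons (residue = amino acid minus water).
# Columns: one_letter	average	monoisotopic
G	57.0519	57.02146
A	71.0788	71.03711
S	87.0782	87.03203
P	97.1167	97.05276
V	99.1326	99.06841
T	101.1051	101.04768
C	103.1388	103.00919
L	113.1594	113.08406
I	113.1594	113.08406
N	114.1038	114.04293
D	115.0886	115.02694
Q	128.1307	128.05858
K	128.1741	128.09496
E	129.1155	129.04259
M	131.1926	131.04049
H	137.1411	137.05891
F	147.1766	147.06841
R	156.1875	156.10111
Y	163.1760	163.06333
W	186.2132	186.07931
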