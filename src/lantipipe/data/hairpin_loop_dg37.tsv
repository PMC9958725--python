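# Hairpin loop initiation free energies at 37 C (kcal/mol) by loop length (nt).
# Lengths beyond 30 are extrapolated logarithmically at evaluation time.
3	5.4
4	5.6
5	5.7
6	5.4
7	6.0
8	6.1
9	6.3
10	6.5
11	6.7
12	6.8
13	6.9
14	7.0
15	7.1
16	7.2
17	7.3
18	7.4
19	7.5
20	7.5
21	7.6
22	7.7
23	7.7
24	7.8
25	7.9
26	7.9
27	8.0
28	8.0
29	8.1
30	8.1
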