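# Methods

This note records the models, conventions, parameter choices, and known
limitations behind `lantipipe`, in the order a user meets them.

## Peptide alignment and variant naming

All identity statements rest on one alignment model: end-to-end global
alignment with BLOSUM62 and affine gap penalties (open 10, extend 0.5).
Percent identity is `100 · identities / compared_columns`, where a
compared column has a residue in both rows. This convention was chosen
because it is invariant to how terminal gaps are counted and reproduces
the community's printed identities for nisin-family pairs: nisin E vs
nisin A gives 24 identities over 32 compared columns = 75.0%, and nisin E
vs nisin U gives 29/31 = 93.5%. (Published summaries of the E–U pair
sometimes print 93.6%; no standard counting convention reproduces that
figure from the sequences, so the package reports the arithmetic 93.5.)

When several alignments are co-optimal, the reported one places gaps as
late in the reference as possible (checked over a capped enumeration of
co-optimal tracebacks). For the nisin E vs A pair the optimum is unique
under this scoring and puts the two-column gap against reference residues
29–30, which is what makes the deletion names ΔSer29/ΔIle30 stable.
Variant names always use 1-based *reference* coordinates even where
upstream deletions shift the query's own numbering (e.g. Val32Phe names
nisin A position 32, which is residue 30 of nisin E). Insertions are
named `insAsn32`-style by the reference position they precede
(`len(ref)+1` for a C-terminal extension).

The engine is Biopython's `PairwiseAligner`; an exhaustive recursive
enumeration over the alignment space serves as the scoring oracle in the
test suite, and the tie-break is validated against the published deletion
names rather than trusted.

Dendrograms use neighbour joining (scikit-bio) on distances
`100 − identity`. Taxa are sorted lexicographically before construction so
the output is independent of input order, and negative branch lengths are
clamped to zero. UPGMA is offered as an alternative
(`lantipipe.variants.upgma_tree`); NJ is the default because it does not
assume a molecular clock.

## Mass model

Residue masses (average and monoisotopic) ship as a plain-text table;
water is 18.0153 / 18.010565 Da. The unmodified mass is the residue sum
plus one water. Lanthipeptide maturation is modelled as `n` dehydrations,
each removing one water from a Ser or Thr; thioether ring closure is
mass-neutral, so `n` is bounded by the Ser+Thr count (8 for nisin E).
Average masses are the headline convention because variant masses are
customarily reported from linear-MALDI spectra; the default matching
tolerance of 1.5 Da reflects that scale (the observed 3100.8 Da sits
0.9 Da from the 8-dehydration prediction of 3101.7 Da). Inference fails
loudly if no count fits or if two fit within tolerance — with ~18 Da
spacing between counts, ambiguity is only possible with tolerances
approaching 9 Da. The packaged table is cross-checked against pyteomics in
the test suite. Adducts, isotope envelopes, and spectrum parsing are out
of scope: observed masses enter as plain numbers.

## Cluster layouts and content classes

A cluster is an ordered list of stranded genes with canonical role labels
(A structural; B/C modification; T transport; I immunity lipoprotein;
P leader peptidase; R/K two-component regulator/kinase; F/E/G
ABC-transporter immunity). The layout string concatenates roles by
leftmost coordinate; comparison counts unordered neighbour pairs shared
between two layouts and breakpoints (adjacencies of one absent from the
other), deliberately orientation-insensitive since operon drawings are
compared as drawn. Content classification is a pure function of the role
set; `immunity_sensing_subset` requires *exactly* {R,K,F,E,G} because that
is the pattern reported across non-producer genomes of the producer
species — any other incomplete set is `partial`. Co-retention of I with P
(the lactococcal nisIP pattern) is not a named category; such genomes
classify as `partial`.

## Regulatory element models

Promoters are modelled as a −35 hexamer and a −10 hexamer at an exact
spacer, scanned on both strands with a per-box Hamming budget (default 1)
and spacer slack (default ±1); `N` never matches. Bundled consensus
models: streptococcal *nisR*-type TGCACA/TATTAC spacer 15; core-peptide
promoter CTGAAC/TACAAT spacer 20; *nisF*-type TGAACA/TATACT spacer 19; and
the peptidase-gene boxes CTGAAC/TAAAAT, whose spacer is not established —
that model is scanned only with an explicit spacer argument (the synthetic
generator uses 17 as its stand-in). A lactococcal-type *nisR* promoter is
a recognized category but its boxes are not bundled; construct a
`PromoterModel` to scan for one. The TCT-N8-TCT direct repeat is matched
exactly, all (overlapping) occurrences reported.

Terminators are inverted repeats (stem 4–15 consecutive pairs, loop
3–10 nt) scored as the sum of nearest-neighbour stacking energies plus a
loop-initiation penalty, both from packaged plain-text tables
(Watson–Crick stack ΔG°37 values of the standard RNA set; hairpin-loop
initiation 5.4–6.5 kcal/mol for loops 3–10, logarithmic beyond). G:U
wobble pairs are off by default and, when enabled, contribute a uniform
−0.5 kcal/mol per stack — a documented simplification. A reported hit
needs ΔG strictly below −5.0 kcal/mol ("stronger than −5.0" read as more
negative; boundary values excluded) plus ≥3 T within 8 nt downstream of
the stem; `strong` means ΔG < −10.0. Overlapping candidates resolve to
the locally strongest per strand (ties broken by position, then longer
stem). These thresholds follow the screening convention used for nisin
clusters, but the energy engine is this package's own documented model,
*not* a reproduction of ARNold: per-cluster terminator counts obtained
with ARNold on the real clusters depend on its unpublished parameters
and external genome sequences, and are treated as qualitative guidance
only — they are not test targets. Output coordinates are 1-based inclusive; internal scanning
is 0-based half-open.

## ORF calling and the pangenome screen

ORFs are maximal: start codon ATG/GTG/TTG (translated Met), genetic code
table 11, read to the first in-frame stop, one ORF per stop per frame
using the most upstream start, default minimum 50 aa, both strands,
deterministic order. ORFs whose translation contains ambiguity (from N
runs) are skipped. A six-frame brute-force scanner is the oracle in
tests.

Homolog assignment aligns each candidate ORF to each reference protein
(same global-alignment model) after a 0.5–2.0× length prefilter, and
keeps the best ORF per role at ≥90% identity — the level at which the
immunity/sensing proteins of non-producer genomes match the producer's,
adopted for all roles since no per-role cut-offs are established. An ORF
may serve two roles only on an exact identity tie (flagged); otherwise
the better role wins and the other falls back to its next candidate.
This ORF-plus-global-alignment design is self-contained and adequate at
desk scale; it does not claim equivalence with seed-and-extend local
search (BLAST) on real genome collections, and screening real NCBI
assemblies is supported through the same CLI but deliberately untested.

## Synthetic data: what it emulates, and what it does not

The generator produces, from a seed: mutated peptides with known edit
lists; operon contigs (back-translated reference proteins in a chosen
layout, planted promoter sites, designed terminator hairpins); and
pangenomes at the reported screening scale — 44 genomes of which 6 carry
the full `PRKAFEGBTCI` operon and 20 carry only `RKFEG`, with coding
genes mutated at the amino-acid level (2% in the standard fixture) and
operon strand and flanking decoy genes varying per genome. All outputs
are pure functions of (parameters, seed), using numpy's `default_rng`;
the packaged reference-protein set draws from a spawn-keyed seed branch
so user seeds cannot replay it.

Reference proteins for roles other than the structural peptide are
**synthetic stand-ins** (random proteins of compact lengths, 90–300 aa —
real modification enzymes are larger; compact sizes keep desk-scale
screening in seconds). Role A is a synthetic 23-residue leader fused to
the derived nisin E core. Back-translation samples synonymous codons
uniformly (no codon-usage model; downstream analysis is protein-level),
and intergenic background is i.i.d. uniform nucleotides with no GC
control.

Designed hairpins bracket both energy thresholds: −18.0 (strong), −10.4
and −9.9 (either side of the strong boundary), −7.6, −5.4 (just inside
the reporting threshold), and −4.9 kcal/mol (just outside; must never be
reported). Arms avoid inner A/T so the loop cannot extend the stem, and
every pair is Watson–Crick so the designed energy is exact under the
packaged tables.

In regulatory test sequences, free background positions are rejection
scrubbed until zero-mismatch scans report exactly the planted manifest:
accidental consensus matches, repeats, stem extensions, and
reverse-strand hairpin twins are disarmed by mutating only non-planted
positions (consensus boxes, motifs, stem arms, and U-tract bases are the
levers; promoter spacers count as background). Planted features are never
moved. On operon contigs the scrub tolerates hairpins wholly inside
coding sequence — terminators within ORFs are biologically real — while
still guaranteeing planted-feature recovery. Consequence for
interpretation: passing recovery tests shows the scanners implement their
definitions exactly on feature-bearing sequence with a clean background;
it says nothing about false-positive rates on real genomic background,
which the thresholds here do not calibrate.

Sequencing artefacts (reads, assembly gaps, SNP-level strain structure)
are not simulated.

## Problem sizes and numerical conventions

The standard test fixture is the 44-genome pangenome (~6–8 kb operon
regions, ~15–20 kb genomes), 200 regulatory sequences of ~300–500 nt, 500
random alignment trials at length ≤8 against the exhaustive oracle, and
50 random 2 kb contigs against the six-frame oracle — sizes chosen so the
full suite runs in well under a minute on one core while every planted
truth is checked exactly. Floats are printed at one decimal for
identities and masses (the field's customary precision); determinism
everywhere comes from explicit seeds, sorted iteration orders, and the
documented alignment/NJ tie-breaks. Degenerate inputs fail loudly rather
than silently: empty sequences, unknown residues/roles, out-of-range
edits, infeasible dehydration counts, sub-site-length scans, and
non-symmetric identity matrices all raise `ValueError` with the offending
value in the message.

## Known limitations

* Lanthionine ring topology, structure, and leader cleavage-site
  prediction are out of scope; leader/core splits are supplied, not
  inferred.
* The terminator energy model is a deliberately small nearest-neighbour
  table, not a full RNA folding engine; energies are comparable within
  this package, not with ViennaRNA/ARNold outputs.
* Homology screening is validated on synthetic genomes only; real
  pangenome counts depend on external data and a local aligner and are
  not asserted anywhere.
* The exact-spacer promoter model cannot represent variable-spacer
  promoters beyond the ±slack window.
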