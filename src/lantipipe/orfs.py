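"""Bacterial ORF calling on nucleotide contigs.

Maximal open reading frames on both strands: start codon in {ATG, GTG,
TTG} (translated to Met per bacterial convention, genetic code table 11),
read through to the first in-frame stop.  One ORF is reported per stop
codon per frame - the longest, i.e. the one using the most upstream start.
Coordinates are 1-based inclusive over the full codon span including the
stop codon, always on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .regulatory import check_dna, revcomp

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
GENETIC_CODE_TABLE = 11


@dataclass(frozen=True)
class OrfRecord:
    contig: str
    start: int
    end: int
    strand: str
    protein_seq: str

    def __post_init__(self) -> None:
        span = self.end - self.start + 1
        if span % 3:
            raise ValueError("ORF span must be divisible by 3")
        if len(self.protein_seq) != span // 3 - 1:
            raise ValueError("protein length inconsistent with codon span")
        if "*" in self.protein_seq:
            raise ValueError("internal stop in ORF translation")


def _translate(cds: str) -> str:
    # start codon becomes Met regardless of its identity
    aa = str(Seq(cds).translate(table=GENETIC_CODE_TABLE))
    return "M" + aa[1:]


def find_orfs(
    contig_seq: str,
    min_aa: int = 50,
    *,
    contig: str = "contig",
    start_codons: tuple = START_CODONS,
) -> list[OrfRecord]:
    """All maximal ORFs of at least ``min_aa`` residues, both strands.

    Deterministic order: sorted by (start, end, strand).
    """
    seq = check_dna(contig_seq)
    n = len(seq)
    records: list[OrfRecord] = []
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            first_start: int | None = None
            for i in range(frame, n - 2, 3):
                codon = s[i:i + 3]
                if codon in STOP_CODONS:
                    if first_start is not None:
                        cds = s[first_start:i + 3]
                        protein = _translate(cds[:-3])
                        if len(protein) >= min_aa and "X" not in protein:
                            if strand == "+":
                                start, end = first_start + 1, i + 3
                            else:
                                start, end = n - (i + 3) + 1, n - first_start
                            records.append(OrfRecord(
                                contig=contig, start=start, end=end,
                                strand=strand, protein_seq=protein,
                            ))
                        first_start = None
                elif first_start is None and codon in start_codons:
                    first_start = i
    records.sort(key=lambda r: (r.start, r.end, r.strand))
    return records
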