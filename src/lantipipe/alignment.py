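"""Global pairwise protein alignment with fixed, documented conventions.

All identity statements in this package (variant diffs, identity matrices,
homolog assignment) rest on the same global alignment model: BLOSUM62
substitution scores with affine gap penalties (open 10, extend 0.5), true
end-to-end (Needleman-Wunsch) alignment.  Percent identity is counted over
columns where both rows carry a residue, so terminal and internal gaps
reduce the comparable length rather than being scored as mismatches.

When several alignments share the optimal score, the reported one is chosen
by a deterministic tie-break: gaps are placed as late as possible in the
reference (first row), which keeps deletion naming stable (a C-terminal
deletion is named at the highest reference coordinate consistent with an
optimal alignment).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice

from Bio import Align
from Bio.Align import substitution_matrices

GAP = "-"
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

#: Number of co-optimal alignments examined by the tie-break.  The headline
#: comparisons in this package (nisin-variant peptides) have a unique
#: optimum; the cap only matters for degenerate low-complexity inputs.
TIE_BREAK_CAP = 64

_MATRICES: dict[str, object] = {}


def _matrix(name: str):
    if name not in _MATRICES:
        _MATRICES[name] = substitution_matrices.load(name)
    return _MATRICES[name]


class InvalidResidueError(ValueError):
    """A sequence contains a symbol outside the 20 canonical amino acids."""


def check_protein(seq: str, *, allow_empty: bool = False) -> str:
    """Validate and return an upper-cased canonical amino-acid string."""
    seq = seq.upper()
    if not seq and not allow_empty:
        raise InvalidResidueError("empty sequence")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise InvalidResidueError(
            f"non-canonical residue(s) {sorted(bad)} in sequence"
        )
    return seq


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of a reference and a query sequence.

    ``aligned_ref``/``aligned_query`` are equal-length strings over residues
    plus ``-``; de-gapping them recovers the input sequences exactly.
    ``compared_columns`` counts columns with a residue in both rows; these
    are the columns over which ``identities`` (and hence percent identity)
    are counted.
    """

    aligned_ref: str
    aligned_query: str
    score: float
    identities: int
    compared_columns: int

    def __post_init__(self) -> None:
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("aligned rows differ in length")
        for a, b in zip(self.aligned_ref, self.aligned_query):
            if a == GAP and b == GAP:
                raise ValueError("gap-gap column in alignment")
        if not 0 <= self.identities <= self.compared_columns:
            raise ValueError("identities exceed compared columns")

    @property
    def ref(self) -> str:
        return self.aligned_ref.replace(GAP, "")

    @property
    def query(self) -> str:
        return self.aligned_query.replace(GAP, "")


def _columns(aligned_ref: str, aligned_query: str) -> tuple[int, int]:
    ident = comp = 0
    for a, b in zip(aligned_ref, aligned_query):
        if a != GAP and b != GAP:
            comp += 1
            if a == b:
                ident += 1
    return ident, comp


def _ref_gap_key(aligned_ref: str, aligned_query: str) -> tuple:
    """Sort key implementing 'gaps as late as possible in the reference'.

    Primary: reference coordinates opposite query-row gaps (deletions),
    maximized.  Secondary: query coordinates opposite reference-row gaps
    (insertions), maximized.
    """
    del_pos = []
    ins_pos = []
    ri = qi = 0
    for a, b in zip(aligned_ref, aligned_query):
        if b == GAP:
            del_pos.append(ri)
        if a == GAP:
            ins_pos.append(qi)
        if a != GAP:
            ri += 1
        if b != GAP:
            qi += 1
    return (tuple(del_pos), tuple(ins_pos))


def global_align(
    a: str,
    b: str,
    *,
    matrix: str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    tie_break: bool = True,
) -> PairwiseAlignment:
    """Globally align two protein sequences.

    Parameters
    ----------
    a, b:
        Reference and query sequences (canonical amino acids only).
    matrix:
        Name of a Biopython substitution matrix.
    gap_open, gap_extend:
        Affine gap penalties, given as positive costs.
    tie_break:
        When True, examine co-optimal alignments (up to ``TIE_BREAK_CAP``)
        and return the one with reference gaps placed latest.  When False,
        return the aligner's first optimum (identical score; used on the
        bulk homology-screening path where only identity matters).
    """
    a = check_protein(a)
    b = check_protein(b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _matrix(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    alns = aligner.align(a, b)
    if tie_break:
        best = max(
            islice(alns, TIE_BREAK_CAP),
            key=lambda aln: _ref_gap_key(str(aln[0]), str(aln[1])),
        )
    else:
        best = alns[0]
    row_ref, row_query = str(best[0]), str(best[1])
    ident, comp = _columns(row_ref, row_query)
    return PairwiseAlignment(
        aligned_ref=row_ref,
        aligned_query=row_query,
        score=float(best.score),
        identities=ident,
        compared_columns=comp,
    )


def percent_identity(aln: PairwiseAlignment) -> float:
    """Percent identity over residue-residue columns, in [0, 100]."""
    if aln.compared_columns == 0:
        raise ValueError("no residue-residue columns to compare")
    return 100.0 * aln.identities / aln.compared_columns


def identity_between(a: str, b: str, **kwargs) -> float:
    """Convenience: percent identity of the optimal global alignment."""
    return percent_identity(global_align(a, b, **kwargs))
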