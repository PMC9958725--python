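"""Core-peptide variant reconstruction, diffing, naming, and relatedness.

A variant is described relative to a reference peptide by an ordered edit
list in *reference* numbering (1-based).  Edit names follow the field's
convention: substitutions like ``Ile4Lys``, deletions like ``ΔSer29``, and
insertions like ``insAsn32`` (the inserted residue takes the reference
coordinate it precedes; an insertion after the last residue takes
``len(ref) + 1``).  Reference numbering is kept even when upstream
deletions shift the query's own coordinates, which is how natural-variant
differences are reported in the literature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import (
    GAP,
    PairwiseAlignment,
    check_protein,
    global_align,
    percent_identity,
)

THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}

_NAME_RE = re.compile(
    r"^(?:(?P<del>Δ|del)(?P<daa>[A-Z][a-z]{2})(?P<dpos>\d+)"
    r"|(?P<ins>ins)(?P<iaa>[A-Z][a-z]{2})(?P<ipos>\d+)"
    r"|(?P<raa>[A-Z][a-z]{2})(?P<spos>\d+)(?P<aaa>[A-Z][a-z]{2}))$"
)

EDIT_KINDS = ("substitution", "deletion", "insertion")


@dataclass(frozen=True)
class Edit:
    """One difference relative to the reference, in reference numbering."""

    kind: str
    ref_pos: int
    ref_aa: str = ""
    alt_aa: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EDIT_KINDS:
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.ref_pos < 1:
            raise ValueError("ref_pos must be 1-based")
        if self.kind == "substitution":
            if not (self.ref_aa and self.alt_aa):
                raise ValueError("substitution needs ref_aa and alt_aa")
            if self.ref_aa == self.alt_aa:
                raise ValueError("substitution must change the residue")
        elif self.kind == "deletion":
            if not self.ref_aa or self.alt_aa:
                raise ValueError("deletion has ref_aa only")
        else:  # insertion
            if self.ref_aa or not self.alt_aa:
                raise ValueError("insertion has alt_aa only")

    @property
    def name(self) -> str:
        if self.kind == "substitution":
            return (
                f"{THREE_LETTER[self.ref_aa]}{self.ref_pos}"
                f"{THREE_LETTER[self.alt_aa]}"
            )
        if self.kind == "deletion":
            return f"Δ{THREE_LETTER[self.ref_aa]}{self.ref_pos}"
        return f"ins{THREE_LETTER[self.alt_aa]}{self.ref_pos}"


def parse_edit_name(name: str) -> Edit:
    """Parse an ``Ile4Lys`` / ``ΔSer29`` / ``insAsn32`` style name."""
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unparseable edit name {name!r}")
    if m.group("del"):
        return Edit("deletion", int(m.group("dpos")),
                    ref_aa=ONE_LETTER[m.group("daa")])
    if m.group("ins"):
        return Edit("insertion", int(m.group("ipos")),
                    alt_aa=ONE_LETTER[m.group("iaa")])
    return Edit("substitution", int(m.group("spos")),
                ref_aa=ONE_LETTER[m.group("raa")],
                alt_aa=ONE_LETTER[m.group("aaa")])


@dataclass(frozen=True)
class PeptideRecord:
    """A named lanthipeptide with optional leader and mandatory core."""

    id: str
    core_seq: str
    variant_name: str = ""
    leader_seq: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "core_seq", check_protein(self.core_seq))
        object.__setattr__(
            self, "leader_seq",
            check_protein(self.leader_seq, allow_empty=True),
        )

    @property
    def precursor(self) -> str:
        return self.leader_seq + self.core_seq


@dataclass
class VariantDiff:
    """Ordered edit list between a reference and a query peptide."""

    ref_id: str
    query_id: str
    edits: list[Edit] = field(default_factory=list)

    def __post_init__(self) -> None:
        last_pos = 0
        last_kind = ""
        for e in self.edits:
            if e.ref_pos < last_pos or (
                e.ref_pos == last_pos and last_kind != "insertion"
            ):
                raise ValueError(
                    "edit positions must increase (an insertion may share "
                    "the position of the edit that follows it)"
                )
            last_pos, last_kind = e.ref_pos, e.kind

    @property
    def name_strings(self) -> list[str]:
        return [e.name for e in self.edits]

    def __len__(self) -> int:
        return len(self.edits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ref_id": self.ref_id, "query_id": self.query_id,
                    "kind": e.kind, "ref_pos": e.ref_pos,
                    "ref_aa": e.ref_aa, "alt_aa": e.alt_aa, "name": e.name,
                }
                for e in self.edits
            ],
            columns=["ref_id", "query_id", "kind", "ref_pos",
                     "ref_aa", "alt_aa", "name"],
        )


def apply_edits(ref_core: str, edits) -> str:
    """Apply an edit list (reference numbering) to a reference peptide.

    Positions are resolved on the original reference, before deletions shift
    coordinates.  Edits may be :class:`Edit` objects or
    ``(kind, ref_pos, ref_aa, alt_aa)`` tuples.
    """
    ref_core = check_protein(ref_core)
    norm: list[Edit] = [
        e if isinstance(e, Edit) else Edit(*e) for e in edits
    ]
    n = len(ref_core)
    seen: set[tuple[str, int]] = set()
    per_pos: dict[int, Edit] = {}
    inserts: dict[int, list[str]] = {}
    for e in norm:
        if e.kind == "insertion":
            if not 1 <= e.ref_pos <= n + 1:
                raise ValueError(f"insertion position {e.ref_pos} outside "
                                 f"1..{n + 1}")
            inserts.setdefault(e.ref_pos, []).append(e.alt_aa)
            continue
        if not 1 <= e.ref_pos <= n:
            raise ValueError(f"position {e.ref_pos} outside reference 1..{n}")
        key = ("sd", e.ref_pos)
        if key in seen:
            raise ValueError(f"duplicate edit at position {e.ref_pos}")
        seen.add(key)
        if ref_core[e.ref_pos - 1] != e.ref_aa:
            raise ValueError(
                f"reference mismatch at {e.ref_pos}: expected "
                f"{e.ref_aa!r}, reference has {ref_core[e.ref_pos - 1]!r}"
            )
        per_pos[e.ref_pos] = e
    out: list[str] = []
    for pos in range(1, n + 2):
        out.extend(inserts.get(pos, ()))
        if pos > n:
            break
        e = per_pos.get(pos)
        if e is None:
            out.append(ref_core[pos - 1])
        elif e.kind == "substitution":
            out.append(e.alt_aa)
        # deletion: emit nothing
    return "".join(out)


def diff_variants(
    ref: PeptideRecord | str, query: PeptideRecord | str
) -> VariantDiff:
    """Derive the edit list from the optimal global alignment."""
    ref_rec = ref if isinstance(ref, PeptideRecord) else PeptideRecord("ref", ref)
    query_rec = (
        query if isinstance(query, PeptideRecord)
        else PeptideRecord("query", query)
    )
    aln = global_align(ref_rec.core_seq, query_rec.core_seq)
    edits: list[Edit] = []
    ref_pos = 0
    for a, b in zip(aln.aligned_ref, aln.aligned_query):
        if a != GAP:
            ref_pos += 1
            if b == GAP:
                edits.append(Edit("deletion", ref_pos, ref_aa=a))
            elif a != b:
                edits.append(Edit("substitution", ref_pos, ref_aa=a, alt_aa=b))
        else:
            edits.append(Edit("insertion", ref_pos + 1, alt_aa=b))
    return VariantDiff(ref_rec.id, query_rec.id, edits)


def hinge_region(
    core: str, ref_core: str | None = None, *, positions=(20, 21, 22)
) -> str:
    """Residues of ``core`` aligned to the reference hinge (positions 20-22).

    The hinge tripeptide links the lipid-II-binding and pore-forming halves
    of nisin-family peptides; by default the reference is mature nisin A.
    Raises if any hinge position is deleted in the query.
    """
    from .refdata import NISIN_A_CORE

    ref_core = NISIN_A_CORE if ref_core is None else check_protein(ref_core)
    aln = global_align(ref_core, check_protein(core))
    wanted = set(positions)
    out: dict[int, str] = {}
    ref_pos = 0
    for a, b in zip(aln.aligned_ref, aln.aligned_query):
        if a != GAP:
            ref_pos += 1
            if ref_pos in wanted:
                if b == GAP:
                    raise ValueError(
                        f"hinge position {ref_pos} is deleted in the query"
                    )
                out[ref_pos] = b
    missing = wanted - out.keys()
    if missing:
        raise ValueError(f"reference lacks hinge positions {sorted(missing)}")
    return "".join(out[p] for p in sorted(out))


@dataclass
class IdentityMatrix:
    """Symmetric percent-identity matrix over labelled peptides."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("diagonal must be 100")
        if v.min() < 0 or v.max() > 100 + 1e-9:
            raise ValueError("identities must lie in [0, 100]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.labels.index(a), self.labels.index(b)]
        )


def identity_matrix(peptides: list[PeptideRecord]) -> IdentityMatrix:
    """All pairwise percent identities of the mature peptides."""
    if len(peptides) < 2:
        raise ValueError("need at least two peptides")
    labels = [p.id for p in peptides]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate peptide ids")
    n = len(peptides)
    v = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(peptides[i].core_seq, peptides[j].core_seq)
            v[i, j] = v[j, i] = percent_identity(aln)
    return IdentityMatrix(labels, v)


def nj_tree(matrix: IdentityMatrix) -> str:
    """Neighbour-joining dendrogram from an identity matrix, as newick.

    Distances are ``100 - identity``.  Taxa are sorted lexicographically
    before construction so the result is deterministic regardless of input
    order; negative branch lengths are clamped to zero.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(matrix.labels) < 3:
        raise ValueError("neighbour joining needs at least three taxa")
    order = sorted(matrix.labels)
    idx = [matrix.labels.index(lbl) for lbl in order]
    dist = 100.0 - matrix.values[np.ix_(idx, idx)]
    np.fill_diagonal(dist, 0.0)
    tree = nj(DistanceMatrix(dist, order), neg_as_zero=True)
    return str(tree).strip()


def upgma_tree(matrix: IdentityMatrix) -> str:
    """UPGMA alternative to :func:`nj_tree` (same distance convention)."""
    from scipy.cluster.hierarchy import average, to_tree
    from scipy.spatial.distance import squareform

    if len(matrix.labels) < 2:
        raise ValueError("need at least two taxa")
    order = sorted(matrix.labels)
    idx = [matrix.labels.index(lbl) for lbl in order]
    dist = 100.0 - matrix.values[np.ix_(idx, idx)]
    np.fill_diagonal(dist, 0.0)
    root = to_tree(average(squareform(dist, checks=False)))

    def newick(node) -> str:
        if node.is_leaf():
            return order[node.id]
        left, right = node.get_left(), node.get_right()
        return (
            f"({newick(left)}:{node.dist - left.dist:.6g},"
            f"{newick(right)}:{node.dist - right.dist:.6g})"
        )

    return newick(root) + ";"
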