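"""Promoter, direct-repeat, and Rho-independent terminator scanning.

Three sequence signals regulate nisin-like operons:

* sigma-70 style promoters: a -35 and a -10 hexamer separated by a fixed
  spacer.  The bundled consensus models are the streptococcal *nisR*
  promoter (TGCACA / TATTAC, 15 nt spacer), the core-peptide promoter
  (CTGAAC / TACAAT, 20 nt), and the *nisF* promoter (TGAACA / TATACT,
  19 nt).  The peptidase-gene promoter boxes (CTGAAC / TAAAAT) are known
  but their spacer is not, so that model requires an explicit spacer.
* a TCT-N8-TCT direct repeat conserved in NisRK-regulated promoters;
* intrinsic (Rho-independent) terminators: an inverted-repeat hairpin
  followed by a U-tract, summarized by a Gibbs free energy from a packaged
  nearest-neighbour stacking table plus a loop-initiation table.  Hits
  require dG below -5.0 kcal/mol; dG below -10.0 kcal/mol is classed
  ``strong``.

Output coordinates are 1-based inclusive on the forward strand; internal
scanning is 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib.resources import files

import pandas as pd

DNA = set("ACGT")
DNA_N = DNA | {"N"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DG_CANDIDATE = -5.0
DG_STRONG = -10.0

#: Stack energy (kcal/mol) assigned to any stack involving a G:U wobble
#: pair; a documented simplification of the packaged Watson-Crick table.
GU_STACK_DG = -0.5


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, *, allow_n: bool = True) -> str:
    seq = seq.upper()
    bad = set(seq) - (DNA_N if allow_n else DNA)
    if bad:
        raise ValueError(f"non-nucleotide symbol(s) {sorted(bad)}")
    return seq


def _load_stacks() -> dict[str, float]:
    text = files("lantipipe.data").joinpath("rna_stack_dg37.tsv").read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, val = line.split("\t")
        table[key] = float(val)
    return table


def _load_loops() -> dict[int, float]:
    text = files("lantipipe.data").joinpath("hairpin_loop_dg37.tsv").read_text()
    table = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        n, val = line.split("\t")
        table[int(n)] = float(val)
    return table


STACK_DG = _load_stacks()
LOOP_DG = _load_loops()

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def is_paired(a: str, b: str, *, allow_gu: bool = False) -> bool:
    """Whether two DNA bases pair in the (RNA) hairpin (T read as U).

    Watson-Crick by default; G:U wobble pairs are accepted when
    ``allow_gu`` is set.
    """
    return (a, b) in _WC or (allow_gu and (a, b) in _GU)


@dataclass(frozen=True)
class PromoterModel:
    """A -35/-10 promoter consensus with a fixed spacer length.

    ``spacer`` may be None for models whose spacer is not established
    (scanning then requires an explicit spacer argument).
    """

    name: str
    box35: str
    box10: str
    spacer: int | None

    def __post_init__(self) -> None:
        for box in (self.box35, self.box10):
            if len(box) != 6 or set(box) - DNA:
                raise ValueError(f"consensus box {box!r} must be an ACGT 6-mer")
        if self.spacer is not None and self.spacer < 0:
            raise ValueError("spacer must be non-negative")


#: Consensus models bundled with the package.  The lactococcal-type nisR
#: promoter (L type) is a recognized category but its boxes are not
#: established here, so no L-type model is bundled; construct a
#: PromoterModel explicitly to scan for one.
BUILTIN_PROMOTERS = {
    "S_type_R": PromoterModel("S_type_R", "TGCACA", "TATTAC", 15),
    "core_A": PromoterModel("core_A", "CTGAAC", "TACAAT", 20),
    "F_type": PromoterModel("F_type", "TGAACA", "TATACT", 19),
    "P_type": PromoterModel("P_type", "CTGAAC", "TAAAAT", None),
}


@dataclass(frozen=True)
class RegulatoryHit:
    """A promoter, direct-repeat, or terminator occurrence.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates of
    the full feature footprint.  Kind-specific attributes are None when not
    applicable.
    """

    kind: str
    contig: str
    strand: str
    start: int
    end: int
    model: str | None = None
    mismatches_35: int | None = None
    mismatches_10: int | None = None
    spacer: int | None = None
    motif_starts: tuple | None = None
    stem_len: int | None = None
    loop_len: int | None = None
    delta_g: float | None = None
    u_tract_length: int | None = None
    strength: str | None = None

    def __post_init__(self) -> None:
        if self.kind == "terminator":
            if self.delta_g is None or self.delta_g >= DG_CANDIDATE:
                raise ValueError(
                    "terminator hits require delta_g below "
                    f"{DG_CANDIDATE} kcal/mol"
                )
            expected = "strong" if self.delta_g < DG_STRONG else "candidate"
            if self.strength != expected:
                raise ValueError(
                    f"strength {self.strength!r} inconsistent with "
                    f"delta_g {self.delta_g}"
                )


def _hamming(window: str, consensus: str) -> int:
    # N never matches a consensus base
    return sum(1 for w, c in zip(window, consensus) if w != c)


def _map_back(start0: int, end0: int, length: int, strand: str):
    """Oriented 0-based half-open -> forward 1-based inclusive."""
    if strand == "+":
        return start0 + 1, end0
    return length - end0 + 1, length - start0


def scan_promoters(
    seq: str,
    model: PromoterModel,
    max_mismatch_per_box: int = 1,
    spacer_slack: int = 1,
    *,
    spacer: int | None = None,
    contig: str = "seq",
    strands: str = "+-",
) -> list[RegulatoryHit]:
    """Find -35/-10 promoter sites on both strands.

    A hit needs each box within ``max_mismatch_per_box`` Hamming mismatches
    of its consensus and a spacer within ``spacer_slack`` of the model's
    exact spacer (or the explicit ``spacer`` override, mandatory for models
    without an established spacer).
    """
    seq = check_dna(seq)
    if max_mismatch_per_box < 0 or spacer_slack < 0:
        raise ValueError("budgets must be non-negative")
    spacer_exact = model.spacer if spacer is None else spacer
    if spacer_exact is None:
        raise ValueError(
            f"model {model.name!r} has no established spacer; pass spacer="
        )
    min_site = 12 + max(spacer_exact - spacer_slack, 0)
    if len(seq) < min_site:
        raise ValueError(
            f"sequence ({len(seq)} nt) shorter than one full site "
            f"({min_site} nt)"
        )
    hits = []
    for strand in strands:
        s = seq if strand == "+" else revcomp(seq)
        for sp in range(max(spacer_exact - spacer_slack, 0),
                        spacer_exact + spacer_slack + 1):
            site_len = 12 + sp
            for i in range(len(s) - site_len + 1):
                m35 = _hamming(s[i:i + 6], model.box35)
                if m35 > max_mismatch_per_box:
                    continue
                j = i + 6 + sp
                m10 = _hamming(s[j:j + 6], model.box10)
                if m10 > max_mismatch_per_box:
                    continue
                start, end = _map_back(i, i + site_len, len(seq), strand)
                hits.append(RegulatoryHit(
                    kind="promoter", contig=contig, strand=strand,
                    start=start, end=end, model=model.name,
                    mismatches_35=m35, mismatches_10=m10, spacer=sp,
                ))
    hits.sort(key=lambda h: (h.start, h.strand, h.spacer))
    return hits


def find_direct_repeats(
    seq: str,
    motif: str = "TCT",
    gap: int = 8,
    *,
    contig: str = "seq",
    strands: str = "+-",
) -> list[RegulatoryHit]:
    """Find motif-N{gap}-motif direct repeats (all occurrences, overlaps
    included)."""
    seq = check_dna(seq)
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = check_dna(motif, allow_n=False)
    if gap < 0:
        raise ValueError("gap must be non-negative")
    k = len(motif)
    hits = []
    for strand in strands:
        s = seq if strand == "+" else revcomp(seq)
        for i in range(len(s) - (2 * k + gap) + 1):
            if s[i:i + k] == motif and s[i + k + gap:i + 2 * k + gap] == motif:
                start, end = _map_back(i, i + 2 * k + gap, len(seq), strand)
                if strand == "+":
                    motif_starts = (start, start + k + gap)
                else:
                    motif_starts = (start, start + k + gap)
                hits.append(RegulatoryHit(
                    kind="direct_repeat", contig=contig, strand=strand,
                    start=start, end=end, motif_starts=motif_starts,
                ))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def loop_penalty(loop_length: int) -> float:
    """Hairpin loop initiation energy; logarithmic beyond the table."""
    if loop_length < 3:
        raise ValueError("hairpin loops shorter than 3 nt are sterically "
                         "impossible")
    if loop_length in LOOP_DG:
        return LOOP_DG[loop_length]
    n_max = max(LOOP_DG)
    return LOOP_DG[n_max] + 1.079 * math.log(loop_length / n_max)


def hairpin_delta_g(stem_pairs, loop_length: int, *,
                    allow_gu: bool = False) -> float:
    """Free energy (kcal/mol) of a hairpin from its base-pair list.

    ``stem_pairs`` is ordered outermost (bottom of the stem) to innermost
    (closing the loop); each element is a ``(left, right)`` DNA base pair
    (T is read as U).  The energy is the sum of nearest-neighbour stacking
    terms over consecutive pairs plus the loop-initiation penalty; more
    negative is stronger.
    """
    pairs = [(a.upper(), b.upper()) for a, b in stem_pairs]
    if len(pairs) < 2:
        raise ValueError("a stem needs at least two consecutive base pairs")
    for a, b in pairs:
        if not is_paired(a, b, allow_gu=allow_gu):
            raise ValueError(f"non-complementary stem pair {a}:{b}")
    dg = loop_penalty(loop_length)
    to_rna = str.maketrans("T", "U")
    for (l1, r1), (l2, r2) in zip(pairs, pairs[1:]):
        if {(l1, r1), (l2, r2)} & _GU:
            dg += GU_STACK_DG
        else:
            key = (l1 + l2 + "/" + r2 + r1).translate(to_rna)
            dg += STACK_DG[key]
    return dg


def _u_tract_length(s: str, stem_end0: int, u_window: int) -> int:
    return s[stem_end0:stem_end0 + u_window].count("T")


def find_terminators(
    seq: str,
    dg_threshold: float = DG_CANDIDATE,
    min_stem: int = 4,
    max_loop: int = 10,
    u_window: int = 8,
    *,
    max_stem: int = 15,
    min_loop: int = 3,
    min_u: int = 3,
    allow_gu: bool = False,
    contig: str = "seq",
    strands: str = "+-",
) -> list[RegulatoryHit]:
    """Predict intrinsic terminators: hairpin + downstream U-tract.

    Enumerates every inverted repeat with ``min_stem <= stem <= max_stem``
    consecutive pairs and a loop of ``min_loop..max_loop`` nt, keeps those
    with ``hairpin_delta_g`` strictly below ``dg_threshold`` and at least
    ``min_u`` T's within ``u_window`` nt downstream of the stem, then
    resolves overlapping candidates (per strand) to the locally strongest.
    Strength is ``strong`` below -10.0 kcal/mol, else ``candidate``.
    """
    seq = check_dna(seq)
    n = len(seq)
    accepted: list[RegulatoryHit] = []
    for strand in strands:
        s = seq if strand == "+" else revcomp(seq)
        candidates = []
        for loop_len in range(min_loop, max_loop + 1):
            for ls in range(1, n - loop_len):
                # extend the stem outward from the loop
                ext = 0
                while (
                    ext < max_stem
                    and ls - 1 - ext >= 0
                    and ls + loop_len + ext < n
                    and is_paired(
                        s[ls - 1 - ext], s[ls + loop_len + ext],
                        allow_gu=allow_gu,
                    )
                ):
                    ext += 1
                for m in range(min_stem, ext + 1):
                    left = s[ls - m:ls]
                    right = s[ls + loop_len:ls + loop_len + m]
                    pairs = [
                        (left[i], right[m - 1 - i]) for i in range(m)
                    ]
                    dg = hairpin_delta_g(pairs, loop_len, allow_gu=allow_gu)
                    if dg >= dg_threshold:
                        continue
                    end0 = ls + loop_len + m
                    u_len = _u_tract_length(s, end0, u_window)
                    if u_len < min_u:
                        continue
                    start, end = _map_back(ls - m, end0, n, strand)
                    candidates.append(RegulatoryHit(
                        kind="terminator", contig=contig, strand=strand,
                        start=start, end=end, stem_len=m, loop_len=loop_len,
                        delta_g=dg, u_tract_length=u_len,
                        strength="strong" if dg < DG_STRONG else "candidate",
                    ))
        # locally strongest wins among overlapping candidates (same strand)
        candidates.sort(
            key=lambda h: (h.delta_g, h.start, h.end, -h.stem_len)
        )
        kept: list[RegulatoryHit] = []
        for cand in candidates:
            if all(
                cand.end < k.start or cand.start > k.end for k in kept
            ):
                kept.append(cand)
        accepted.extend(kept)
    accepted.sort(key=lambda h: (h.start, h.strand, h.end))
    return accepted


# -- output ------------------------------------------------------------------

def hits_to_bed(hits) -> pd.DataFrame:
    """BED-like 6-column table: contig, start-1, end, name, score, strand.

    Score is -dG for terminators and the total mismatch count for
    promoters (0 for repeats).
    """
    rows = []
    for h in hits:
        if h.kind == "terminator":
            name = f"terminator_{h.strength}"
            score = round(-h.delta_g, 2)
        elif h.kind == "promoter":
            name = f"promoter_{h.model}"
            score = h.mismatches_35 + h.mismatches_10
        else:
            name = "direct_repeat"
            score = 0
        rows.append({
            "contig": h.contig, "start": h.start - 1, "end": h.end,
            "name": name, "score": score, "strand": h.strand,
        })
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "name", "score", "strand"]
    )


def hits_to_records(hits) -> list[dict]:
    """JSON-ready detailed report."""
    out = []
    for h in hits:
        d = {k: v for k, v in h.__dict__.items() if v is not None}
        if "motif_starts" in d:
            d["motif_starts"] = list(d["motif_starts"])
        out.append(d)
    return out
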