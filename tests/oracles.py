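"""Independent oracles used by the test suite.

These deliberately re-derive results from first principles (exhaustive
recursion, six-frame scanning, direct table summation) rather than calling
the library's own code paths, so agreement is meaningful.
"""

from __future__ import annotations

from functools import lru_cache
from io import StringIO
from math import inf

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def exhaustive_global_score(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Optimal global affine-gap score by exhaustive recursion over the
    alignment space (memoized on (i, j, gap-state))."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        out = -inf
        if i < len(a) and j < len(b):
            out = max(out, _BLOSUM62[a[i], b[j]] + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "U" else gap_open
            out = max(out, -cost + best(i + 1, j, "U"))
        if j < len(b):
            cost = gap_extend if state == "L" else gap_open
            out = max(out, -cost + best(i, j + 1, "L"))
        return out

    return best(0, 0, "M")


_CODE = CodonTable.unambiguous_dna_by_id[11]
_RC = str.maketrans("ACGTN", "TGCAN")


def sixframe_orfs(seq: str, min_aa: int, starts=("ATG", "GTG", "TTG")):
    """Brute-force maximal-ORF scan: returns a set of
    (start, end, strand, protein) tuples, 1-based inclusive forward
    coordinates spanning start codon through stop codon."""
    seq = seq.upper()
    n = len(seq)
    found = set()
    for strand in "+-":
        s = seq if strand == "+" else seq.translate(_RC)[::-1]
        for frame in range(3):
            codons = [
                (i, s[i:i + 3]) for i in range(frame, n - 2, 3)
            ]
            start_idx = None
            for i, codon in codons:
                if codon in _CODE.stop_codons:
                    if start_idx is not None:
                        cds = s[start_idx:i]
                        protein = "M" + "".join(
                            _CODE.forward_table.get(cds[k:k + 3], "X")
                            for k in range(3, len(cds), 3)
                        )
                        if len(protein) >= min_aa and "X" not in protein:
                            if strand == "+":
                                coords = (start_idx + 1, i + 3)
                            else:
                                coords = (n - (i + 3) + 1, n - start_idx)
                            found.add((*coords, strand, protein))
                        start_idx = None
                elif start_idx is None and codon in starts:
                    start_idx = i
    return found


def _load_table(name: str, parse_key):
    from importlib.resources import files

    table = {}
    for line in files("lantipipe.data").joinpath(name).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, val = line.split("\t")
        table[parse_key(key)] = float(val)
    return table


def hand_summed_hairpin_dg(arm_left: str, arm_right: str,
                           loop_len: int) -> float:
    """Sum the packaged stack/loop tables directly for a WC hairpin whose
    pairs are (arm_left[i], arm_right[-1-i]) from the stem bottom up."""
    stacks = _load_table("rna_stack_dg37.tsv", str)
    loops = _load_table("hairpin_loop_dg37.tsv", int)
    to_rna = str.maketrans("T", "U")
    m = len(arm_left)
    pairs = [(arm_left[i], arm_right[m - 1 - i]) for i in range(m)]
    dg = loops[loop_len]
    for (l1, r1), (l2, r2) in zip(pairs, pairs[1:]):
        dg += stacks[(l1 + l2 + "/" + r2 + r1).translate(to_rna)]
    return dg


def brute_force_terminators(
    seq: str,
    dg_fn,
    dg_threshold: float = -5.0,
    min_stem: int = 4,
    max_stem: int = 15,
    max_loop: int = 10,
    u_window: int = 8,
    min_u: int = 3,
):
    """Enumerate every (position, stem, loop) combination directly and apply
    the documented filters and the locally-strongest overlap rule.

    ``dg_fn(pairs, loop_len)`` evaluates energies; pass the packaged-table
    evaluator.  Returns (start, end, strand, round(dg, 6)) tuples.
    """
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    seq = seq.upper()
    n = len(seq)
    results = []
    for strand in "+-":
        s = seq if strand == "+" else seq.translate(_RC)[::-1]
        cands = []
        for i in range(n):  # 0-based stem start
            for m in range(min_stem, max_stem + 1):
                for loop in range(3, max_loop + 1):
                    j = i + m + loop  # right arm start
                    if j + m > n:
                        continue
                    left = s[i:i + m]
                    right = s[j:j + m]
                    pairs = [(left[k], right[m - 1 - k]) for k in range(m)]
                    if any(p not in wc for p in pairs):
                        continue
                    dg = dg_fn(pairs, loop)
                    if dg >= dg_threshold:
                        continue
                    if s[j + m:j + m + u_window].count("T") < min_u:
                        continue
                    if strand == "+":
                        start, end = i + 1, j + m
                    else:
                        start, end = n - (j + m) + 1, n - i
                    cands.append((dg, start, end, m, loop))
        cands.sort(key=lambda t: (t[0], t[1], t[2], -t[3]))
        kept = []
        for dg, start, end, m, loop in cands:
            if all(end < ks or start > ke for _, ks, ke in kept):
                kept.append((dg, start, end))
        results += [
            (start, end, strand, round(dg, 6)) for dg, start, end in kept
        ]
    return sorted(results)


def tree_bipartitions(newick: str) -> set[frozenset]:
    """Non-trivial tip bipartitions of a tree; both sides of every split
    are included, so membership tests can use either side."""
    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(tips) - 1:
            splits.add(side)
            splits.add(tips - side)
    return splits
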