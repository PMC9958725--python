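"""Packaged reference data: nisin core peptides and cluster role proteins.

The mature (leaderless) nisin A sequence and the published edit lists are
the primary anchors; the nisin E, U, and Z cores are *derived* from them at
import time by applying the edit lists, so the derivation itself is
exercised every time the package is used.

The eleven cluster role proteins (A, B, T, C, I, P, R, K, F, E, G) are
SYNTHETIC stand-ins: real nisin-cluster protein sequences are not bundled,
so roles other than the structural peptide are represented by
deterministically generated random proteins of plausible (compact) lengths.
They serve as homology-screen references for synthetic genomes only and
carry no biological sequence information.
"""

from __future__ import annotations

import numpy as np

#: Mature (leaderless) nisin A, 34 residues.
NISIN_A_CORE = "ITSISLCTPGCKTGALMGCNMKTATCHCSIHVSK"

#: Published differences of nisin E relative to nisin A (reference
#: numbering): eight substitutions and two deletions.
NISIN_E_EDITS = [
    ("substitution", 4, "I", "K"),
    ("substitution", 18, "G", "T"),
    ("substitution", 20, "N", "P"),
    ("substitution", 21, "M", "I"),
    ("substitution", 27, "H", "G"),
    ("deletion", 29, "S", ""),
    ("deletion", 30, "I", ""),
    ("substitution", 32, "V", "F"),
    ("substitution", 33, "S", "G"),
    ("substitution", 34, "K", "N"),
]

#: Differences of nisin U relative to nisin E (nisin E numbering): nisin U
#: carries Ile where nisin E has Ala15, Leu where nisin E has Ile21, and
#: lacks the C-terminal Asn32.
NISIN_U_EDITS_FROM_E = [
    ("substitution", 15, "A", "I"),
    ("substitution", 21, "I", "L"),
    ("deletion", 32, "N", ""),
]

#: Nisin Z differs from nisin A by the single substitution His27Asn.
NISIN_Z_EDITS = [("substitution", 27, "H", "N")]


def _apply(ref: str, edits) -> str:
    out = []
    table = {pos: (kind, alt) for kind, pos, _ref_aa, alt in edits}
    for i, aa in enumerate(ref, start=1):
        kind, alt = table.get(i, (None, None))
        if kind == "deletion":
            continue
        out.append(alt if kind == "substitution" else aa)
    return "".join(out)


NISIN_E_CORE = _apply(NISIN_A_CORE, NISIN_E_EDITS)
NISIN_U_CORE = _apply(NISIN_E_CORE, NISIN_U_EDITS_FROM_E)
NISIN_Z_CORE = _apply(NISIN_A_CORE, NISIN_Z_EDITS)

#: The four bundled core peptides, keyed by variant letter.
CORE_PEPTIDES = {
    "A": NISIN_A_CORE,
    "Z": NISIN_Z_CORE,
    "E": NISIN_E_CORE,
    "U": NISIN_U_CORE,
}

#: Canonical cluster role labels, no layout implied.
CLUSTER_ROLES = ("A", "B", "T", "C", "I", "P", "R", "K", "F", "E", "G")

#: Gene orders of the nisin A and nisin E clusters as drawn left to right.
NISIN_A_LAYOUT = "ABTCIPRKFEG"
NISIN_E_LAYOUT = "PRKAFEGBTCI"

#: Roles retained by the immunity/sensing-only genomes.
IMMUNITY_SENSING_ROLES = frozenset("RKFEG")

# Compact lengths for the synthetic role proteins.  Real modification and
# transport proteins are larger; these sizes keep desk-scale screening fast
# while preserving the length diversity the homology screen has to handle.
_ROLE_LENGTHS = {
    "B": 300, "T": 250, "C": 140, "I": 110, "P": 240,
    "R": 100, "K": 180, "F": 90, "E": 120, "G": 110,
}

_AA = "ACDEFGHIKLMNPQRSTVWY"
# Fixed: the reference set is a package constant.  The spawn key puts the
# stream in a different branch of the seed tree from any user-supplied
# integer seed, so simulated decoy genes can never replay these draws.
_REFERENCE_SEED = np.random.SeedSequence(20230208, spawn_key=(1,))


def _synthetic_protein(rng: np.random.Generator, n: int) -> str:
    body = rng.choice(list(_AA), size=n - 1)
    return "M" + "".join(body)


def reference_proteins() -> dict[str, str]:
    """Return the role -> protein map used for homology screening.

    Role A is a synthetic 23-residue leader fused to the derived nisin E
    core (precursor-like); all other roles are synthetic proteins, generated
    from a fixed internal seed so the reference set is a package constant.
    """
    rng = np.random.default_rng(_REFERENCE_SEED)
    refs = {"A": _synthetic_protein(rng, 24) + NISIN_E_CORE}
    for role in CLUSTER_ROLES:
        if role == "A":
            continue
        refs[role] = _synthetic_protein(rng, _ROLE_LENGTHS[role])
    return refs
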