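"""Dehydration-aware peptide mass model.

Lanthipeptide maturation dehydrates Ser/Thr residues (loss of one water,
~18.02 Da, per event) before cysteine thioethers close the lanthionine
rings; ring formation itself is mass-neutral.  The observable mature mass
is therefore the unmodified peptide mass minus ``n`` waters, with ``n``
bounded by the Ser+Thr count.  Average masses are the headline convention
(linear-MALDI scale); monoisotopic values are available throughout.

Residue masses come from a packaged plain-text table
(``data/residue_masses.tsv``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

from .alignment import check_protein

WATER = {"average": 18.0153, "monoisotopic": 18.010565}

#: Default mass-match tolerance in Da, suited to linear MALDI-TOF data.
DEFAULT_TOLERANCE = 1.5

_KINDS = ("average", "monoisotopic")


def _load_residue_masses() -> dict[str, dict[str, float]]:
    table: dict[str, dict[str, float]] = {k: {} for k in _KINDS}
    text = files("lantipipe.data").joinpath("residue_masses.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, avg, mono = line.split("\t")
        table["average"][aa] = float(avg)
        table["monoisotopic"][aa] = float(mono)
    return table


RESIDUE_MASSES = _load_residue_masses()


def _check_kind(kind: str) -> str:
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    return kind


def dehydratable_residues(seq: str) -> int:
    """Number of Ser + Thr residues (upper bound on dehydrations)."""
    return sum(seq.count(aa) for aa in "ST")


def peptide_mass(seq: str, kind: str = "average") -> float:
    """Unmodified peptide mass: residue sum plus one water, in Da."""
    seq = check_protein(seq)
    _check_kind(kind)
    masses = RESIDUE_MASSES[kind]
    return sum(masses[aa] for aa in seq) + WATER[kind]


def modified_mass(seq: str, n_dehydrations: int, kind: str = "average") -> float:
    """Peptide mass after ``n_dehydrations`` water losses, in Da."""
    seq = check_protein(seq)
    if n_dehydrations < 0:
        raise ValueError("n_dehydrations must be non-negative")
    limit = dehydratable_residues(seq)
    if n_dehydrations > limit:
        raise ValueError(
            f"{n_dehydrations} dehydrations requested but only {limit} "
            f"Ser/Thr residues present"
        )
    return peptide_mass(seq, kind) - n_dehydrations * WATER[kind]


@dataclass(frozen=True)
class DehydrationInference:
    """Best-matching dehydration count for an observed mass."""

    sequence: str
    kind: str
    n_dehydrations: int
    predicted_mass: float
    observed_mass: float

    @property
    def residual(self) -> float:
        return self.observed_mass - self.predicted_mass


def infer_dehydrations(
    seq: str,
    observed_mass: float,
    tolerance: float = DEFAULT_TOLERANCE,
    kind: str = "average",
) -> DehydrationInference:
    """Infer the dehydration count explaining an observed mature mass.

    Returns the unique ``n`` in ``[0, #Ser+#Thr]`` minimizing the absolute
    residual, provided that residual is within ``tolerance``.  Raises if no
    count fits or if two counts tie within tolerance (only possible for
    tolerances approaching half a water mass).
    """
    seq = check_protein(seq)
    _check_kind(kind)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    base = peptide_mass(seq, kind)
    w = WATER[kind]
    candidates = [
        (abs(observed_mass - (base - n * w)), n)
        for n in range(dehydratable_residues(seq) + 1)
    ]
    candidates.sort()
    best_resid, best_n = candidates[0]
    if best_resid > tolerance:
        raise ValueError(
            f"no dehydration count within {tolerance} Da of "
            f"{observed_mass} Da (closest: n={best_n}, "
            f"off by {best_resid:.2f} Da)"
        )
    if len(candidates) > 1 and candidates[1][0] <= tolerance:
        raise ValueError(
            f"ambiguous match: n={best_n} and n={candidates[1][1]} both "
            f"within {tolerance} Da"
        )
    return DehydrationInference(
        sequence=seq,
        kind=kind,
        n_dehydrations=best_n,
        predicted_mass=base - best_n * w,
        observed_mass=observed_mass,
    )
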