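"""Pangenome presence/absence screen for nisin-cluster genes.

Each genome is reduced to its ORF set; every canonical cluster role is then
assigned to the ORF with the highest global-alignment percent identity to
that role's reference protein, provided the identity clears a threshold
(default 90%, the level at which the immunity/sensing proteins of
non-producer genomes match the producer's).  The detected role set is
classified with the same rules as annotated clusters
(:func:`lantipipe.clusters.classify_cluster`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alignment import identity_between
from .clusters import CATEGORIES, classify_cluster
from .io import read_fasta
from .orfs import OrfRecord, find_orfs
from .refdata import CLUSTER_ROLES

DEFAULT_ID_THRESHOLD = 90.0

#: Candidate ORFs are aligned to a reference only if their length lies
#: within this ratio band of the reference length (speed prefilter; a true
#: homolog at <=10% divergence cannot fall outside it).
LENGTH_RATIO_BAND = (0.5, 2.0)


@dataclass(frozen=True)
class HomologHit:
    role: str
    orf: OrfRecord
    percent_identity: float
    tied: bool = False


@dataclass
class GenomeClassification:
    genome_id: str
    category: str
    role_hits: dict = field(default_factory=dict)

    @property
    def present_roles(self) -> frozenset:
        return frozenset(self.role_hits)


def assign_homologs(
    orfs,
    references: dict[str, str],
    id_threshold: float = DEFAULT_ID_THRESHOLD,
) -> dict[str, HomologHit]:
    """Best reference homolog per role among the ORFs.

    One ORF may serve several roles only when its identities to those
    references tie exactly (flagged ``tied``); otherwise the ORF goes to
    the role it matches best and the other roles fall back to their next
    best candidate above the threshold.
    """
    if not references:
        raise ValueError("references must be non-empty")
    lo, hi = LENGTH_RATIO_BAND
    # identity of every plausible (role, orf) pair
    scored: dict[str, list[tuple[float, int]]] = {}
    for role, ref in references.items():
        rows = []
        for k, orf in enumerate(orfs):
            ratio = len(orf.protein_seq) / len(ref)
            if not lo <= ratio <= hi:
                continue
            pid = identity_between(ref, orf.protein_seq, tie_break=False)
            if pid >= id_threshold:
                rows.append((pid, k))
        rows.sort(key=lambda t: (-t[0], t[1]))
        scored[role] = rows
    # resolve ORFs claimed by several roles
    assigned: dict[str, HomologHit] = {}
    taken: set[int] = set()
    pointer = {role: 0 for role in scored}
    while True:
        claims: dict[int, list[tuple[float, str]]] = {}
        for role, rows in scored.items():
            if role in assigned:
                continue
            while pointer[role] < len(rows) and rows[pointer[role]][1] in taken:
                pointer[role] += 1
            if pointer[role] < len(rows):
                pid, k = rows[pointer[role]]
                claims.setdefault(k, []).append((pid, role))
        if not claims:
            break
        for k, claimants in claims.items():
            best_pid = max(pid for pid, _ in claimants)
            winners = [role for pid, role in claimants if pid == best_pid]
            tied = len(winners) > 1
            taken.add(k)
            for role in winners:
                assigned[role] = HomologHit(
                    role=role, orf=orfs[k],
                    percent_identity=best_pid, tied=tied,
                )
            for pid, role in claimants:
                if role not in winners:
                    pointer[role] += 1  # try this role's next candidate
    return assigned


def classify_genome(
    genome,
    references: dict[str, str] | None = None,
    id_threshold: float = DEFAULT_ID_THRESHOLD,
    *,
    genome_id: str | None = None,
    min_aa: int = 50,
) -> GenomeClassification:
    """ORF-call, homolog-assign, and classify one genome.

    ``genome`` is a FASTA path or a ``{contig_id: sequence}`` mapping.
    """
    if references is None:
        from .refdata import reference_proteins

        references = reference_proteins()
    if isinstance(genome, (str, Path)):
        contigs = read_fasta(genome)
        genome_id = genome_id or Path(genome).stem
    else:
        contigs = dict(genome)
        genome_id = genome_id or "genome"
    if not contigs or all(not s for s in contigs.values()):
        raise ValueError(f"genome {genome_id!r} has no sequence")
    orfs: list[OrfRecord] = []
    for name in sorted(contigs):
        orfs.extend(find_orfs(contigs[name], min_aa=min_aa, contig=name))
    hits = assign_homologs(orfs, references, id_threshold)
    cls = classify_cluster(hits.keys(), cluster_id=genome_id)
    return GenomeClassification(
        genome_id=genome_id, category=cls.category, role_hits=hits
    )


def summarize_pangenome(classifications) -> pd.DataFrame:
    """Category counts and fractions over a set of genomes."""
    classifications = list(classifications)
    if not classifications:
        raise ValueError("need at least one genome")
    counts = {cat: 0 for cat in CATEGORIES}
    for c in classifications:
        counts[c.category] += 1
    total = len(classifications)
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "fraction": [counts[c] / total for c in CATEGORIES],
        }
    )


def classification_table(classifications) -> pd.DataFrame:
    """Per-genome table: genome, category, roles, identities."""
    rows = []
    for c in classifications:
        rows.append({
            "genome_id": c.genome_id,
            "category": c.category,
            "roles": "".join(r for r in CLUSTER_ROLES if r in c.role_hits),
            "identities": ";".join(
                f"{r}={c.role_hits[r].percent_identity:.1f}"
                for r in CLUSTER_ROLES if r in c.role_hits
            ),
        })
    return pd.DataFrame(
        rows, columns=["genome_id", "category", "roles", "identities"]
    )
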