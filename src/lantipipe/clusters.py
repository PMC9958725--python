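"""Gene-cluster layout modelling, comparison, and content classification.

Nisin-like clusters are modelled as ordered, stranded genes carrying one of
the eleven canonical role labels (A structural peptide; B/C modification;
T transport; I immunity lipoprotein; P leader peptidase; R/K two-component
regulator/kinase; F/E/G ABC-transporter immunity).  Layouts are compared as
unordered adjacency sets (synteny breakpoints), and a genome's nisin gene
content is classified from the *set* of roles present:

* ``full_production`` - all eleven roles;
* ``immunity_sensing_subset`` - exactly {R, K, F, E, G}, the
  regulator/kinase plus ABC-transporter immunity genes with no production
  machinery;
* ``none`` - no roles at all;
* ``partial`` - anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .refdata import CLUSTER_ROLES, IMMUNITY_SENSING_ROLES

ROLE_SET = frozenset(CLUSTER_ROLES)

CATEGORIES = ("full_production", "immunity_sensing_subset", "partial", "none")


@dataclass(frozen=True)
class GeneRecord:
    role: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.role not in ROLE_SET:
            raise ValueError(f"unknown role label {self.role!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"bad coordinates {self.start}..{self.end} (1-based "
                f"inclusive, start <= end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class GeneClusterModel:
    cluster_id: str
    genes: list[GeneRecord] = field(default_factory=list)

    def sorted_genes(self) -> list[GeneRecord]:
        return sorted(self.genes, key=lambda g: (g.contig, g.start, g.end))


@dataclass(frozen=True)
class ClusterClassification:
    cluster_id: str
    category: str
    present_roles: frozenset
    missing_roles: frozenset


def layout_string(cluster: GeneClusterModel, *,
                  allow_overlap: bool = False) -> str:
    """Role labels concatenated in genomic order (leftmost first).

    ``allow_overlap`` relaxes the non-overlap invariant, appropriate for
    clusters reconstructed from called ORFs, whose spans may extend past a
    neighbour's coordinates.
    """
    genes = cluster.sorted_genes()
    roles = [g.role for g in genes]
    if len(set(roles)) != len(roles):
        dupes = sorted({r for r in roles if roles.count(r) > 1})
        raise ValueError(f"duplicate role label(s) {dupes} in cluster")
    if not allow_overlap:
        prev_end: dict[str, int] = {}
        for g in genes:
            if g.start <= prev_end.get(g.contig, 0):
                raise ValueError(
                    f"overlapping genes on contig {g.contig} near {g.start}"
                )
            prev_end[g.contig] = g.end
    return "".join(roles)


def _adjacencies(layout: str) -> set[frozenset]:
    return {frozenset(pair) for pair in zip(layout, layout[1:])}


def compare_layouts(
    c1: GeneClusterModel | str, c2: GeneClusterModel | str
) -> dict[str, int]:
    """Shared unordered adjacencies and breakpoints between two layouts.

    A breakpoint is an adjacency of the first layout absent from the
    second; the comparison is orientation-insensitive (a layout and its
    reversal are zero breakpoints apart).
    """
    l1 = c1 if isinstance(c1, str) else layout_string(c1)
    l2 = c2 if isinstance(c2, str) else layout_string(c2)
    if set(l1) != set(l2):
        raise ValueError(
            f"layouts are over different role sets: {sorted(set(l1))} vs "
            f"{sorted(set(l2))}"
        )
    a1, a2 = _adjacencies(l1), _adjacencies(l2)
    return {
        "shared_adjacencies": len(a1 & a2),
        "breakpoints": len(a1 - a2),
    }


def classify_cluster(
    present_roles, cluster_id: str = ""
) -> ClusterClassification:
    """Classify a cluster (or genome) from its set of detected roles."""
    present = frozenset(present_roles)
    unknown = present - ROLE_SET
    if unknown:
        raise ValueError(f"unknown role label(s) {sorted(unknown)}")
    if present == ROLE_SET:
        category = "full_production"
    elif present == IMMUNITY_SENSING_ROLES:
        category = "immunity_sensing_subset"
    elif not present:
        category = "none"
    else:
        category = "partial"
    return ClusterClassification(
        cluster_id=cluster_id,
        category=category,
        present_roles=present,
        missing_roles=ROLE_SET - present,
    )


# -- tab-separated interchange ------------------------------------------------

_TSV_COLUMNS = ["cluster_id", "role", "contig", "start", "end", "strand"]


def read_cluster_tsv(path) -> dict[str, GeneClusterModel]:
    """Read clusters from TSV (cluster_id, role, contig, start, end, strand).

    Coordinates are 1-based inclusive.  Returns a dict keyed by cluster_id.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cluster TSV missing column(s) {sorted(missing)}")
    clusters: dict[str, GeneClusterModel] = {}
    for row in df.itertuples(index=False):
        rec = GeneRecord(
            role=row.role, contig=row.contig,
            start=int(row.start), end=int(row.end), strand=row.strand,
        )
        clusters.setdefault(
            row.cluster_id, GeneClusterModel(row.cluster_id)
        ).genes.append(rec)
    return clusters


def write_cluster_tsv(clusters, path) -> None:
    rows = [
        {
            "cluster_id": c.cluster_id, "role": g.role, "contig": g.contig,
            "start": g.start, "end": g.end, "strand": g.strand,
        }
        for c in clusters
        for g in c.sorted_genes()
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def classification_frame(classifications) -> pd.DataFrame:
    """Tabulate classifications (one row per cluster/genome)."""
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "category": c.category,
                "present_roles": "".join(sorted(c.present_roles)),
                "missing_roles": "".join(sorted(c.missing_roles)),
            }
            for c in classifications
        ],
        columns=["cluster_id", "category", "present_roles", "missing_roles"],
    )
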