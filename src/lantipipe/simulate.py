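"""Seeded synthetic inputs with exact truth manifests.

Everything downstream of this module is exercised on data generated here:
peptides with known edit lists, contigs carrying nisin-like operons with
planted promoters / direct repeats / designed terminator hairpins, and
multi-genome pangenomes mirroring the reported prevalence of nisin E
gene content in its producer species (44 genomes:
6 with the full production operon, 20 with the immunity/sensing subset,
the rest with decoy genes only).

All outputs are pure functions of their parameters and a seed.  Background
sequence is i.i.d. uniform nucleotides, with one deliberate exception: in
regulatory test sequences, free (non-planted) positions are rejection
scrubbed until the scanners report exactly the planted features, so the
manifest is exact ground truth.  Planted features themselves are never
moved or altered by scrubbing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from . import regulatory
from .clusters import GeneClusterModel, GeneRecord
from .refdata import (
    IMMUNITY_SENSING_ROLES,
    NISIN_E_LAYOUT,
    reference_proteins,
)
from .regulatory import PromoterModel, revcomp
from .variants import Edit

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = np.array(list("ACGT"))

#: Spacer assumed when planting/scanning a promoter model whose spacer is
#: not established (the peptidase-gene model).
DEFAULT_TEST_SPACER = 17


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed)
    )


def random_dna(n: int, seed) -> str:
    return "".join(_rng(seed).choice(_NT, size=n))


# -- peptides -----------------------------------------------------------------

def mutate_peptide(ref: str, n_subs: int, n_dels: int, seed):
    """Random substitutions/deletions at non-overlapping positions.

    Returns ``(sequence, edits)`` with the edit list in reference numbering
    (the same convention :func:`lantipipe.variants.apply_edits` consumes).
    """
    rng = _rng(seed)
    ref = ref.upper()
    total = n_subs + n_dels
    if total >= len(ref):
        raise ValueError("more edits than reference positions")
    positions = sorted(
        rng.choice(np.arange(1, len(ref) + 1), size=total, replace=False)
    )
    kinds = np.array(["substitution"] * n_subs + ["deletion"] * n_dels)
    rng.shuffle(kinds)
    edits = []
    for pos, kind in zip(positions, kinds):
        ref_aa = ref[pos - 1]
        if kind == "substitution":
            alt = ref_aa
            while alt == ref_aa:
                alt = str(rng.choice(list(_AA)))
            edits.append(Edit("substitution", int(pos), ref_aa, alt))
        else:
            edits.append(Edit("deletion", int(pos), ref_aa))
    from .variants import apply_edits

    return apply_edits(ref, edits), edits


def mutate_protein(protein: str, rate: float, rng) -> str:
    """Per-residue substitutions at ``rate`` (position 1 Met preserved)."""
    rng = _rng(rng)
    out = list(protein)
    for i in range(1, len(out)):
        if rng.random() < rate:
            alt = out[i]
            while alt == out[i]:
                alt = str(rng.choice(list(_AA)))
            out[i] = alt
    return "".join(out)


# -- coding sequence synthesis ------------------------------------------------

_table = CodonTable.unambiguous_dna_by_id[11]
_CODONS: dict[str, list[str]] = {}
for codon, aa in _table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
_STOPS = tuple(sorted(_table.stop_codons))


def back_translate(protein: str, rng) -> str:
    """Protein -> CDS with uniformly sampled synonymous codons plus a stop.

    The initial Met is encoded as ATG so the gene has a canonical start.
    """
    rng = _rng(rng)
    if not protein.startswith("M"):
        raise ValueError("synthetic proteins must start with Met")
    codons = ["ATG"]
    codons += [
        str(rng.choice(_CODONS[aa])) for aa in protein[1:]
    ]
    codons.append(str(rng.choice(list(_STOPS))))
    return "".join(codons)


# -- manifests ----------------------------------------------------------------

@dataclass
class SyntheticManifest:
    """Ground truth for a generated dataset (JSON round-trippable)."""

    seed: int
    features: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "features": self.features},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticManifest":
        obj = json.loads(text)
        return cls(seed=obj["seed"], features=obj["features"])

    def of_kind(self, kind: str) -> list[dict]:
        return [f for f in self.features if f["kind"] == kind]


# -- designed terminator hairpins --------------------------------------------

@dataclass(frozen=True)
class HairpinDesign:
    """A terminator hairpin: 5' arm, loop, U-tract tail.

    The 3' arm is the reverse complement of ``arm``, so every stem pair is
    Watson-Crick; the free energy is fully determined by the packaged
    tables.
    """

    name: str
    arm: str
    loop: str = "TTTT"
    tail: str = "TTTTTTTT"

    @property
    def sequence(self) -> str:
        return self.arm + self.loop + revcomp(self.arm) + self.tail

    @property
    def stem_footprint(self) -> int:
        return 2 * len(self.arm) + len(self.loop)

    @property
    def delta_g(self) -> float:
        right = revcomp(self.arm)
        m = len(self.arm)
        pairs = [(self.arm[i], right[m - 1 - i]) for i in range(m)]
        return regulatory.hairpin_delta_g(pairs, len(self.loop))

    @property
    def expected_strength(self) -> str | None:
        dg = self.delta_g
        if dg >= regulatory.DG_CANDIDATE:
            return None  # below reporting threshold
        return "strong" if dg < regulatory.DG_STRONG else "candidate"


#: Fixed designs bracketing the two energy thresholds (dG from the
#: packaged tables, loop TTTT): strong -18.0, borderline_strong -10.4,
#: just_candidate -9.9, candidate -7.6, borderline_weak -5.4, and a
#: subthreshold design at -4.9 that must never be reported.
HAIRPIN_DESIGNS = {
    "strong": HairpinDesign("strong", "AGGCGCGCC"),
    "borderline_strong": HairpinDesign("borderline_strong", "CGCCGAC"),
    "just_candidate": HairpinDesign("just_candidate", "GCACTCC"),
    "candidate": HairpinDesign("candidate", "GAGAAGC"),
    "borderline_weak": HairpinDesign("borderline_weak", "ACACTC"),
    "subthreshold": HairpinDesign("subthreshold", "TCGCG"),
}


# -- regulatory test sequences ------------------------------------------------

@dataclass
class _Assembly:
    """Accumulates planted segments and tracks fixed (immutable) spans."""

    rng: np.random.Generator
    parts: list[str] = field(default_factory=list)
    fixed: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open
    length: int = 0

    def add_background(self, n: int) -> None:
        self.parts.append(random_dna(n, self.rng))
        self.length += n

    def add_fixed(self, seq: str, *, guard: tuple[int, int] = (0, 0)) -> int:
        """Append a planted segment; returns its 1-based start.

        ``guard`` extends the immutable span (upstream, downstream) beyond
        the segment itself (e.g. a terminator's U-tract windows).
        """
        start0 = self.length
        self.parts.append(seq)
        self.length += len(seq)
        self.fixed.append((max(start0 - guard[0], 0),
                           self.length + guard[1]))
        return start0 + 1

    def add_promoter(self, model: PromoterModel, spacer: int) -> int:
        """Plant a promoter site; only the boxes are immutable (the spacer
        is arbitrary background and stays scrubbable).  Returns the
        1-based start of the full site."""
        start = self.add_fixed(model.box35)
        self.add_background(spacer)
        self.add_fixed(model.box10)
        return start

    def sequence(self) -> list[str]:
        return list("".join(self.parts))


def _scrub(
    seq: list[str],
    fixed_spans,
    expected,
    scan,
    rng,
    max_rounds: int = 60,
    strict: bool = True,
) -> str:
    """Resample free positions until ``scan`` reports exactly ``expected``.

    ``expected`` is a set of (kind, start, end, strand) tuples; ``scan``
    maps a sequence string to hits.  In strict mode an unwanted hit with no
    free position to break is an error (never the case for features planted
    in pure background); with ``strict=False`` such hits are tolerated -
    appropriate for contigs with coding genes, where hairpins inside a CDS
    are realistic and immutable - but the planted features themselves must
    still all be recovered.
    """
    def is_free(pos0: int) -> bool:
        return not any(a <= pos0 < b for a, b in fixed_spans)

    for _ in range(max_rounds):
        text = "".join(seq)
        hits = scan(text)
        got = {(h.kind, h.start, h.end, h.strand) for h in hits}
        extra = [h for h in hits
                 if (h.kind, h.start, h.end, h.strand) not in expected]
        if not extra and expected - got:
            # a planted feature is masked by something other than a
            # scrubbable extra hit - cannot happen for background planting
            raise RuntimeError(
                f"planted feature(s) not recovered: {expected - got}"
            )
        progress = False
        for h in extra:
            # only positions that actually disarm the hit: consensus boxes
            # and motifs (not spacers/gaps), stem arms (not the loop), and
            # T's in the U-tract window
            lo, hi = h.start - 1, h.end  # 0-based half-open footprint
            if h.kind == "promoter":
                levers = list(range(lo, lo + 6)) + list(range(hi - 6, hi))
            elif h.kind == "direct_repeat":
                levers = list(range(lo, lo + 3)) + list(range(hi - 3, hi))
            else:  # terminator: break a stem pair or deplete the U-tract
                m = h.stem_len
                levers = list(range(lo, lo + m)) + list(range(hi - m, hi))
                if h.strand == "+":
                    window = range(hi, min(hi + 8, len(seq)))
                    u_base = "T"
                else:  # the minus-strand U-tract reads as forward-strand A
                    window = range(max(lo - 8, 0), lo)
                    u_base = "A"
                levers += [p for p in window if seq[p] == u_base]
            free = [p for p in levers if is_free(p)]
            if not free:
                if strict:
                    raise RuntimeError(
                        f"cannot scrub accidental {h.kind} at "
                        f"{h.start}-{h.end}"
                    )
                continue
            progress = True
            pos = int(rng.choice(free))
            old = seq[pos]
            while seq[pos] == old:
                seq[pos] = str(rng.choice(_NT))
        if not progress:
            if expected - got:
                raise RuntimeError(
                    f"planted feature(s) not recovered: {expected - got}"
                )
            return text
    raise RuntimeError("background scrubbing did not converge")


def make_regulatory_sequence(
    seed,
    promoter_model: PromoterModel | None = None,
    hairpins=("strong", "just_candidate", "subthreshold"),
    plant_repeat: bool = True,
    pad: int = 60,
):
    """A background contig with planted regulatory features and manifest.

    Plants one promoter site (exact consensus, exact spacer), optionally a
    TCT-N8-TCT direct repeat, and the named hairpin designs (each followed
    by its U-tract), separated by ``pad`` nt of background.  Free
    background is scrubbed so that zero-mismatch scans recover exactly the
    planted features.
    """
    rng = _rng(seed)
    if promoter_model is None:
        promoter_model = regulatory.BUILTIN_PROMOTERS["S_type_R"]
    spacer = promoter_model.spacer
    if spacer is None:
        spacer = DEFAULT_TEST_SPACER
    manifest = SyntheticManifest(
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1
    )
    asm = _Assembly(rng=rng)
    asm.add_background(pad)

    start = asm.add_promoter(promoter_model, spacer)
    site_len = 12 + spacer
    manifest.features.append({
        "kind": "promoter", "model": promoter_model.name, "strand": "+",
        "start": start, "end": start + site_len - 1, "spacer": spacer,
    })
    asm.add_background(pad)

    if plant_repeat:
        repeat = "TCT" + random_dna(8, rng) + "TCT"
        start = asm.add_fixed(repeat)
        manifest.features.append({
            "kind": "direct_repeat", "strand": "+",
            "start": start, "end": start + len(repeat) - 1,
        })
        asm.add_background(pad)

    for name in hairpins:
        design = HAIRPIN_DESIGNS[name]
        start = asm.add_fixed(design.sequence)
        strength = design.expected_strength
        feat = {
            "kind": "terminator", "design": name, "strand": "+",
            "delta_g": round(design.delta_g, 3),
            "reported": strength is not None,
        }
        if strength is not None:
            feat.update({
                "start": start, "end": start + design.stem_footprint - 1,
                "strength": strength,
            })
        manifest.features.append(feat)
        asm.add_background(pad)

    expected = set()
    for f in manifest.features:
        if f["kind"] == "terminator" and not f["reported"]:
            continue
        expected.add((f["kind"], f["start"], f["end"], f["strand"]))

    def scan(text: str):
        hits = []
        for model in regulatory.BUILTIN_PROMOTERS.values():
            explicit = None
            if model.spacer is None:
                # spacer-less models are scanned at the spacer used for
                # planting (or the conventional test spacer)
                explicit = (
                    spacer if model.name == promoter_model.name
                    else DEFAULT_TEST_SPACER
                )
            hits += regulatory.scan_promoters(
                text, model, max_mismatch_per_box=0, spacer_slack=0,
                spacer=explicit,
            )
        hits += regulatory.find_direct_repeats(text)
        hits += regulatory.find_terminators(text)
        return hits

    seq = _scrub(asm.sequence(), asm.fixed, expected, scan, rng)
    return seq, manifest


# -- gene clusters ------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPromoter:
    model: PromoterModel
    upstream_of: str
    spacer: int | None = None


@dataclass(frozen=True)
class PlantedTerminator:
    design: HairpinDesign
    after: str


def make_cluster_sequence(
    layout: str = NISIN_E_LAYOUT,
    include_promoters=(),
    include_terminators=(),
    seed=0,
    *,
    proteins: dict[str, str] | None = None,
    mutation_rate: float = 0.0,
    intergenic: int = 80,
    flank: int = 250,
    strand: str = "+",
    contig_id: str = "contig_1",
    scrub: bool = False,
):
    """Back-translate an operon layout into a contig, with truth manifest.

    Genes follow ``layout`` left to right; requested promoter sites go in
    the intergenic gap 5' of their gene, designed terminator hairpins 3'
    of theirs.  With ``strand='-'`` the finished contig is
    reverse-complemented (coordinates in the returned model and manifest
    are re-mapped).  Returns ``(sequence, GeneClusterModel, manifest)``.
    """
    rng = _rng(seed)
    proteins = proteins or reference_proteins()
    unknown = set(layout) - set(proteins)
    if unknown:
        raise ValueError(f"layout roles {sorted(unknown)} have no protein")
    promoters_by_role: dict[str, list[PlantedPromoter]] = {}
    for p in include_promoters:
        promoters_by_role.setdefault(p.upstream_of, []).append(p)
    terminators_by_role: dict[str, list[PlantedTerminator]] = {}
    for t in include_terminators:
        terminators_by_role.setdefault(t.after, []).append(t)
    for role in list(promoters_by_role) + list(terminators_by_role):
        if role not in set(layout):
            raise ValueError(f"placement refers to role {role!r} not in layout")

    manifest = SyntheticManifest(
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1
    )
    asm = _Assembly(rng=rng)
    asm.add_background(flank)
    genes: list[GeneRecord] = []
    for role in layout:
        for planted in promoters_by_role.get(role, ()):  # 5' features
            spacer = (
                planted.spacer if planted.spacer is not None
                else planted.model.spacer
            )
            if spacer is None:
                raise ValueError(
                    f"promoter {planted.model.name!r} needs an explicit spacer"
                )
            start = asm.add_promoter(planted.model, spacer)
            manifest.features.append({
                "kind": "promoter", "model": planted.model.name,
                "strand": "+", "start": start,
                "end": start + 12 + spacer - 1, "spacer": spacer,
                "upstream_of": role,
            })
            asm.add_background(intergenic // 2)
        protein = proteins[role]
        if mutation_rate > 0:
            protein = mutate_protein(protein, mutation_rate, rng)
        cds = back_translate(protein, rng)
        start = asm.add_fixed(cds)
        genes.append(GeneRecord(
            role=role, contig=contig_id, start=start,
            end=start + len(cds) - 1, strand="+",
        ))
        manifest.features.append({
            "kind": "gene", "role": role, "strand": "+",
            "start": start, "end": start + len(cds) - 1,
            "protein_length": len(protein),
        })
        for planted in terminators_by_role.get(role, ()):  # 3' features
            asm.add_background(intergenic // 2)
            design = planted.design
            start = asm.add_fixed(design.sequence)
            strength = design.expected_strength
            feat = {
                "kind": "terminator", "design": design.name, "strand": "+",
                "delta_g": round(design.delta_g, 3),
                "reported": strength is not None, "after": planted.after,
            }
            if strength is not None:
                feat.update({
                    "start": start,
                    "end": start + design.stem_footprint - 1,
                    "strength": strength,
                })
            manifest.features.append(feat)
        asm.add_background(intergenic)
    asm.add_background(max(flank - intergenic, 0))

    if scrub:
        expected = {
            (f["kind"], f["start"], f["end"], f["strand"])
            for f in manifest.features
            if f["kind"] in ("promoter", "direct_repeat")
            or (f["kind"] == "terminator" and f["reported"])
        }

        def scan(text: str):
            hits = []
            for model in regulatory.BUILTIN_PROMOTERS.values():
                if model.spacer is None:
                    continue
                hits += regulatory.scan_promoters(
                    text, model, max_mismatch_per_box=0, spacer_slack=0
                )
            hits += regulatory.find_terminators(text)
            return hits

        seq = _scrub(asm.sequence(), asm.fixed, expected, scan, rng,
                     strict=False)
    else:
        seq = "".join(asm.parts)

    if strand == "-":
        n = len(seq)
        seq = revcomp(seq)
        genes = [
            GeneRecord(
                role=g.role, contig=g.contig,
                start=n - g.end + 1, end=n - g.start + 1, strand="-",
            )
            for g in genes
        ]
        for f in manifest.features:
            if "start" in f:
                f["start"], f["end"] = n - f["end"] + 1, n - f["start"] + 1
                f["strand"] = "-"
    cluster = GeneClusterModel(cluster_id=contig_id, genes=genes)
    return seq, cluster, manifest


# -- pangenomes ---------------------------------------------------------------

def make_pangenome(
    n_genomes: int = 44,
    n_full: int = 6,
    n_subset: int = 20,
    mutation_rate: float = 0.02,
    seed=0,
    *,
    n_decoys: int = 6,
):
    """Synthetic pangenome emulating the reported gene-content mix.

    ``n_full`` genomes carry the complete operon (layout PRKAFEGBTCI),
    ``n_subset`` carry only the RKFEG immunity/sensing genes, and the rest
    carry decoy genes only.  Coding genes are mutated at the amino-acid
    level at ``mutation_rate``; operon strand and flanking decoys vary per
    genome.  Returns ``(genomes, manifest)`` with genomes as
    ``{genome_id: {contig_id: seq}}``.
    """
    if n_full + n_subset > n_genomes:
        raise ValueError("n_full + n_subset exceeds n_genomes")
    if not 0 <= mutation_rate <= 0.1:
        raise ValueError("mutation_rate must be within [0, 0.1]")
    rng = _rng(seed)
    proteins = reference_proteins()
    categories = (
        ["full_production"] * n_full
        + ["immunity_sensing_subset"] * n_subset
        + ["none"] * (n_genomes - n_full - n_subset)
    )
    order = rng.permutation(n_genomes)
    manifest = SyntheticManifest(
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1
    )
    genomes: dict[str, dict[str, str]] = {}
    for idx in range(n_genomes):
        genome_id = f"genome_{idx + 1:03d}"
        category = categories[order[idx]]
        if category == "full_production":
            layout = NISIN_E_LAYOUT
        elif category == "immunity_sensing_subset":
            layout = "".join(
                r for r in NISIN_E_LAYOUT if r in IMMUNITY_SENSING_ROLES
            )
        else:
            layout = ""
        strand = "+" if rng.random() < 0.5 else "-"
        parts = []
        # leading decoy genes in random background
        for _ in range(n_decoys):
            decoy_len = int(rng.integers(60, 320))
            decoy = "M" + "".join(rng.choice(list(_AA), size=decoy_len - 1))
            parts.append(random_dna(int(rng.integers(40, 160)), rng))
            parts.append(back_translate(decoy, rng))
        if layout:
            op_seq, _cluster, _m = make_cluster_sequence(
                layout, seed=rng, proteins=proteins,
                mutation_rate=mutation_rate, strand=strand,
            )
            parts.append(op_seq)
        parts.append(random_dna(int(rng.integers(100, 300)), rng))
        genomes[genome_id] = {"contig_1": "".join(parts)}
        manifest.features.append({
            "kind": "genome", "genome_id": genome_id,
            "category": category, "operon_strand": strand if layout else None,
        })
    return genomes, manifest


def write_pangenome(genomes, manifest, outdir) -> None:
    """Materialize a pangenome as one FASTA per genome plus manifest.json."""
    from .io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome_id in sorted(genomes):
        write_fasta(genomes[genome_id], outdir / f"{genome_id}.fasta")
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
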