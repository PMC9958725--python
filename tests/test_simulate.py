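import numpy as np
import pytest

from lantipipe import BUILTIN_PROMOTERS, NISIN_A_CORE
from lantipipe.clusters import layout_string
from lantipipe.regulatory import find_terminators, scan_promoters
from lantipipe.simulate import (
    HAIRPIN_DESIGNS,
    PlantedPromoter,
    PlantedTerminator,
    SyntheticManifest,
    back_translate,
    make_cluster_sequence,
    make_pangenome,
    make_regulatory_sequence,
    mutate_peptide,
    mutate_protein,
)


class TestMutatePeptide:
    def test_edit_counts_match_request(self):
        seq, edits = mutate_peptide(NISIN_A_CORE, 8, 2, seed=0)
        kinds = [e.kind for e in edits]
        assert kinds.count("substitution") == 8
        assert kinds.count("deletion") == 2
        assert len(seq) == 32

    def test_zero_edits_returns_reference(self):
        seq, edits = mutate_peptide(NISIN_A_CORE, 0, 0, seed=1)
        assert seq == NISIN_A_CORE and edits == []

    def test_same_seed_reproduces(self):
        assert mutate_peptide(NISIN_A_CORE, 5, 1, 7) \
            == mutate_peptide(NISIN_A_CORE, 5, 1, 7)

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError, match="more edits"):
            mutate_peptide("ACDEF", 4, 1, 0)


def test_mutate_protein_preserves_start_and_length():
    protein = "M" + "ACDEFGHIKL" * 10
    out = mutate_protein(protein, 0.3, np.random.default_rng(0))
    assert out[0] == "M" and len(out) == len(protein)
    assert out != protein


def test_back_translation_round_trips():
    from Bio.Seq import Seq

    protein = "MKTAYIAKQR"
    cds = back_translate(protein, 3)
    assert len(cds) == 3 * (len(protein) + 1)
    assert str(Seq(cds[:-3]).translate(table=11)) == protein


def test_manifest_round_trips_through_json():
    _, manifest = make_regulatory_sequence(seed=2)
    back = SyntheticManifest.from_json(manifest.to_json())
    assert back == manifest


class TestRegulatorySequence:
    def test_same_seed_is_byte_identical(self):
        a, _ = make_regulatory_sequence(seed=12)
        b, _ = make_regulatory_sequence(seed=12)
        assert a == b

    def test_manifest_features_locatable(self):
        seq, manifest = make_regulatory_sequence(seed=13)
        for f in manifest.features:
            if "start" in f:
                assert 1 <= f["start"] <= f["end"] <= len(seq)


class TestClusterSequence:
    def test_layout_and_planted_features_recovered(self):
        planted_prom = PlantedPromoter(BUILTIN_PROMOTERS["S_type_R"], "R")
        planted_term = PlantedTerminator(HAIRPIN_DESIGNS["strong"], "I")
        seq, cluster, manifest = make_cluster_sequence(
            "PRKAFEGBTCI",
            include_promoters=[planted_prom],
            include_terminators=[planted_term],
            seed=3,
            scrub=True,
        )
        assert layout_string(cluster) == "PRKAFEGBTCI"
        prom_hits = {
            (h.start, h.end)
            for h in scan_promoters(seq, BUILTIN_PROMOTERS["S_type_R"], 0, 0)
        }
        for f in manifest.of_kind("promoter"):
            assert (f["start"], f["end"]) in prom_hits
        term_hits = {
            (h.start, h.end): h.strength for h in find_terminators(seq)
        }
        for f in manifest.of_kind("terminator"):
            if f["reported"]:
                assert term_hits[(f["start"], f["end"])] == f["strength"]

    def test_empty_layout_gives_plain_contig(self):
        seq, cluster, manifest = make_cluster_sequence("", seed=4)
        assert cluster.genes == [] and manifest.of_kind("gene") == []
        assert set(seq) <= set("ACGT")

    def test_same_seed_is_byte_identical(self):
        a, _, _ = make_cluster_sequence("RKFEG", seed=5)
        b, _, _ = make_cluster_sequence("RKFEG", seed=5)
        assert a == b

    def test_minus_strand_mirrors_coordinates(self):
        fwd, cf, mf = make_cluster_sequence("RKFEG", seed=6, strand="+")
        rev, cr, mr = make_cluster_sequence("RKFEG", seed=6, strand="-")
        assert len(fwd) == len(rev)
        n = len(fwd)
        for gf, gr in zip(cf.sorted_genes(), reversed(cr.sorted_genes())):
            assert (gr.start, gr.end) == (n - gf.end + 1, n - gf.start + 1)
            assert gr.strand == "-"

    def test_unknown_placement_role_rejected(self):
        with pytest.raises(ValueError, match="not in layout"):
            make_cluster_sequence(
                "RKFEG",
                include_promoters=[
                    PlantedPromoter(BUILTIN_PROMOTERS["S_type_R"], "A")
                ],
                seed=7,
            )


class TestPangenome:
    def test_category_mix_matches_request(self):
        genomes, manifest = make_pangenome(10, 2, 3, 0.01, seed=8)
        assert len(genomes) == 10
        cats = [f["category"] for f in manifest.of_kind("genome")]
        assert cats.count("full_production") == 2
        assert cats.count("immunity_sensing_subset") == 3
        assert cats.count("none") == 5

    def test_same_seed_is_byte_identical(self):
        a, ma = make_pangenome(4, 1, 1, 0.02, seed=9)
        b, mb = make_pangenome(4, 1, 1, 0.02, seed=9)
        assert a == b and ma == mb

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_pangenome(3, 2, 2, 0.0, seed=0)
        with pytest.raises(ValueError, match="mutation_rate"):
            make_pangenome(3, 1, 1, 0.5, seed=0)

    def test_write_pangenome_materializes_files(self, tmp_path):
        genomes, manifest = make_pangenome(3, 1, 1, 0.0, seed=10)
        from lantipipe.simulate import write_pangenome

        write_pangenome(genomes, manifest, tmp_path)
        fastas = sorted(p.name for p in tmp_path.glob("*.fasta"))
        assert fastas == ["genome_001.fasta", "genome_002.fasta",
                          "genome_003.fasta"]
        back = SyntheticManifest.from_json(
            (tmp_path / "manifest.json").read_text()
        )
        assert back == manifest
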