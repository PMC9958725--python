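import pytest

import oracles
from lantipipe.regulatory import (
    BUILTIN_PROMOTERS,
    DG_CANDIDATE,
    DG_STRONG,
    PromoterModel,
    find_direct_repeats,
    find_terminators,
    hairpin_delta_g,
    hits_to_bed,
    revcomp,
    scan_promoters,
)
from lantipipe.simulate import (
    HAIRPIN_DESIGNS,
    make_regulatory_sequence,
    random_dna,
)

S_TYPE = BUILTIN_PROMOTERS["S_type_R"]


class TestPromoters:
    def test_planted_consensus_site_found_exactly(self):
        site = S_TYPE.box35 + random_dna(15, 7) + S_TYPE.box10
        seq = random_dna(40, 1) + site + random_dna(40, 2)
        hits = scan_promoters(seq, S_TYPE, 0, 0)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        h = fwd[0]
        assert (h.start, h.end, h.spacer) == (41, 41 + 26, 15)
        assert h.mismatches_35 == h.mismatches_10 == 0

    def test_scrubbed_background_has_no_hits(self):
        seq, _ = make_regulatory_sequence(
            seed=99, hairpins=(), plant_repeat=False,
            promoter_model=BUILTIN_PROMOTERS["core_A"],
        )
        assert scan_promoters(seq, S_TYPE, 0, 0) == []

    def test_one_mismatch_found_only_with_budget(self):
        box35 = "AGCACA"  # one substitution in TGCACA
        site = box35 + random_dna(15, 3) + S_TYPE.box10
        seq = "C" * 30 + site + "C" * 30
        assert scan_promoters(seq, S_TYPE, 0, 0) == []
        hits = scan_promoters(seq, S_TYPE, 1, 0)
        assert len(hits) == 1 and hits[0].mismatches_35 == 1

    def test_n_never_matches(self):
        site = S_TYPE.box35 + random_dna(15, 3) + "NATTAC"
        seq = "C" * 30 + site + "C" * 30
        assert scan_promoters(seq, S_TYPE, 0, 0) == []

    def test_strand_symmetry(self):
        seq, _ = make_regulatory_sequence(seed=11, hairpins=())
        n = len(seq)
        fwd = scan_promoters(seq, S_TYPE, 1, 1)
        rev = scan_promoters(revcomp(seq), S_TYPE, 1, 1)
        mirrored = {(n - h.end + 1, n - h.start + 1,
                     "-" if h.strand == "+" else "+") for h in rev}
        assert {(h.start, h.end, h.strand) for h in fwd} == mirrored

    def test_relaxing_budget_never_removes_hits(self):
        seq = random_dna(400, 5)
        tight = scan_promoters(seq, S_TYPE, 0, 0)
        loose = scan_promoters(seq, S_TYPE, 2, 1)
        keys = {(h.start, h.end, h.strand) for h in loose}
        assert all((h.start, h.end, h.strand) in keys for h in tight)

    def test_model_without_spacer_needs_explicit_argument(self):
        seq = random_dna(100, 1)
        with pytest.raises(ValueError, match="spacer"):
            scan_promoters(seq, BUILTIN_PROMOTERS["P_type"], 0, 0)
        # and with a spacer supplied it scans fine
        scan_promoters(seq, BUILTIN_PROMOTERS["P_type"], 0, 0, spacer=17)

    def test_sequence_shorter_than_site_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            scan_promoters("ACGT", S_TYPE, 0, 0)


class TestDirectRepeats:
    def test_planted_repeat_found(self):
        repeat = "TCT" + random_dna(8, 13) + "TCT"
        seq = "G" * 25 + repeat + "G" * 25
        hits = [h for h in find_direct_repeats(seq) if h.strand == "+"]
        assert [(h.start, h.end) for h in hits] == [(26, 26 + 13)]

    def test_absent_repeat(self):
        assert find_direct_repeats("G" * 200) == []

    def test_overlapping_motifs_counted_by_exhaustive_scan(self):
        seq = "TCTTCTAAAAAAAATCT"
        hits = [h for h in find_direct_repeats(seq) if h.strand == "+"]
        # only the second TCT sits exactly 8 nt before the third
        assert [(h.start, h.end) for h in hits] == [(4, 17)]


class TestHairpinEnergy:
    def test_gc_stem_matches_hand_summed_tables(self):
        arm = "GCGCGCGC"
        right = revcomp(arm)
        pairs = [(arm[i], right[len(arm) - 1 - i]) for i in range(len(arm))]
        expected = oracles.hand_summed_hairpin_dg(arm, right, 4)
        assert hairpin_delta_g(pairs, 4) == pytest.approx(expected)
        assert expected < DG_STRONG

    def test_two_au_pairs_are_weak(self):
        dg = hairpin_delta_g([("A", "T"), ("A", "T")], 3)
        assert dg == pytest.approx(
            oracles.hand_summed_hairpin_dg("AA", "TT", 3)
        )
        assert dg > DG_CANDIDATE

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="two consecutive"):
            hairpin_delta_g([("G", "C")], 4)

    def test_non_complementary_pair_rejected(self):
        with pytest.raises(ValueError, match="non-complementary"):
            hairpin_delta_g([("G", "C"), ("A", "G")], 4)

    def test_wobble_pair_requires_opt_in(self):
        from lantipipe.regulatory import GU_STACK_DG, loop_penalty

        pairs = [("G", "T"), ("G", "C"), ("C", "G")]
        with pytest.raises(ValueError):
            hairpin_delta_g(pairs, 4)
        dg = hairpin_delta_g(pairs, 4, allow_gu=True)
        gc_on_cg_stack = oracles.hand_summed_hairpin_dg("GC", "GC", 4) \
            - loop_penalty(4)
        assert dg == pytest.approx(
            loop_penalty(4) + GU_STACK_DG + gc_on_cg_stack
        )

    def test_designed_hairpins_straddle_the_thresholds(self):
        dg = {name: d.delta_g for name, d in HAIRPIN_DESIGNS.items()}
        assert dg["strong"] < DG_STRONG
        assert DG_STRONG < dg["just_candidate"] < DG_CANDIDATE
        assert dg["subthreshold"] >= DG_CANDIDATE
        assert dg["borderline_strong"] < DG_STRONG < dg["candidate"]
        assert DG_STRONG < dg["borderline_weak"] < DG_CANDIDATE


class TestTerminators:
    def test_planted_strong_hairpin_found_and_classed(self):
        design = HAIRPIN_DESIGNS["strong"]
        # flanks chosen not to pair with the stem ends or the U-tract
        seq = "C" * 50 + design.sequence + "A" * 50
        hits = find_terminators(seq)
        ours = [h for h in hits if h.strand == "+"]
        assert len(ours) == 1
        h = ours[0]
        assert (h.start, h.end) == (51, 50 + design.stem_footprint)
        assert h.strength == "strong"
        assert h.delta_g == pytest.approx(design.delta_g)
        assert h.u_tract_length >= 3

    def test_poly_a_has_no_terminators(self):
        assert find_terminators("A" * 300) == []

    def test_subthreshold_design_excluded(self):
        design = HAIRPIN_DESIGNS["subthreshold"]
        assert design.delta_g > DG_CANDIDATE
        seq = "C" * 50 + design.sequence + "A" * 50
        assert find_terminators(seq) == []

    def test_missing_u_tract_excludes_hairpin(self):
        design = HAIRPIN_DESIGNS["strong"]
        naked = design.arm + design.loop + revcomp(design.arm)
        seq = "A" * 50 + naked + "G" * 50
        assert [h for h in find_terminators(seq) if h.strand == "+"] == []

    def test_every_hit_satisfies_its_own_invariants(self):
        seq, _ = make_regulatory_sequence(
            seed=21, hairpins=tuple(HAIRPIN_DESIGNS),
        )
        for h in find_terminators(seq):
            assert h.delta_g < DG_CANDIDATE
            assert (h.strength == "strong") == (h.delta_g < DG_STRONG)
            assert h.u_tract_length >= 3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_enumerator_on_short_sequences(self, seed):
        seq = random_dna(200, seed)
        got = sorted(
            (h.start, h.end, h.strand, round(h.delta_g, 6))
            for h in find_terminators(seq)
        )
        expected = oracles.brute_force_terminators(seq, hairpin_delta_g)
        assert got == expected

    def test_brute_force_agreement_with_planted_hairpin(self):
        design = HAIRPIN_DESIGNS["just_candidate"]
        seq = random_dna(80, 5) + design.sequence + random_dna(80, 6)
        got = sorted(
            (h.start, h.end, h.strand, round(h.delta_g, 6))
            for h in find_terminators(seq)
        )
        assert got == oracles.brute_force_terminators(seq, hairpin_delta_g)


def test_bed_output_shape():
    seq, _ = make_regulatory_sequence(seed=4)
    hits = (
        scan_promoters(seq, S_TYPE, 0, 0)
        + find_direct_repeats(seq)
        + find_terminators(seq)
    )
    bed = hits_to_bed(hits)
    assert list(bed.columns) == ["contig", "start", "end", "name", "score",
                                 "strand"]
    assert (bed["end"] > bed["start"]).all()


def test_promoter_model_validation():
    with pytest.raises(ValueError, match="6-mer"):
        PromoterModel("bad", "TGCAC", "TATTAC", 15)
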