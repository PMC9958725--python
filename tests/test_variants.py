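import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from lantipipe import (
    Edit,
    PeptideRecord,
    apply_edits,
    diff_variants,
    hinge_region,
    identity_matrix,
    nj_tree,
    parse_edit_name,
)
from lantipipe.refdata import NISIN_E_EDITS, NISIN_U_EDITS_FROM_E
from lantipipe.simulate import mutate_peptide
from lantipipe.variants import IdentityMatrix, upgma_tree


class TestApplyEdits:
    def test_published_edit_list_reconstructs_nisin_e(self, cores):
        assert apply_edits(cores["A"], NISIN_E_EDITS) == cores["E"]
        assert len(cores["E"]) == 32

    def test_empty_edit_list_is_identity(self, cores):
        assert apply_edits(cores["A"], []) == cores["A"]

    def test_nisin_u_derived_from_nisin_e(self, cores):
        assert apply_edits(cores["E"], NISIN_U_EDITS_FROM_E) == cores["U"]
        assert len(cores["U"]) == 31

    def test_reference_mismatch_is_an_error(self, cores):
        with pytest.raises(ValueError, match="reference mismatch"):
            apply_edits(cores["A"], [Edit("substitution", 4, "W", "K")])

    def test_duplicate_position_is_an_error(self, cores):
        with pytest.raises(ValueError, match="duplicate"):
            apply_edits(cores["A"], [
                Edit("substitution", 4, "I", "K"),
                Edit("deletion", 4, "I"),
            ])

    def test_position_outside_reference_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            apply_edits("ACDEF", [Edit("deletion", 6, "F")])

    def test_cterminal_insertion_appends(self):
        assert apply_edits("ACD", [Edit("insertion", 4, alt_aa="W")]) == "ACDW"


class TestDiffVariants:
    def test_nisin_e_vs_a_published_names(self, cores):
        diff = diff_variants(
            PeptideRecord("A", cores["A"]), PeptideRecord("E", cores["E"])
        )
        assert diff.name_strings == [
            "Ile4Lys", "Gly18Thr", "Asn20Pro", "Met21Ile", "His27Gly",
            "ΔSer29", "ΔIle30", "Val32Phe", "Ser33Gly", "Lys34Asn",
        ]
        assert len(diff) == 10

    def test_identical_sequences_give_empty_diff(self, cores):
        assert len(diff_variants(cores["A"], cores["A"])) == 0

    def test_nisin_u_to_e_three_differences(self, cores):
        diff = diff_variants(cores["U"], cores["E"])
        kinds = [e.kind for e in diff.edits]
        assert len(diff) == 3
        assert kinds.count("substitution") == 2
        assert kinds.count("insertion") == 1
        assert [e.ref_pos for e in diff.edits if e.kind == "substitution"] \
            == [15, 21]

    @settings(derandomize=True, max_examples=40)
    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=15, max_size=40),
        st.integers(0, 6),
        st.integers(0, 3),
        st.integers(0, 2**31 - 1),
    )
    def test_round_trip_apply_then_diff(self, ref, n_subs, n_dels, seed):
        """diff_variants recovers a query that apply_edits reproduces."""
        query, _true_edits = mutate_peptide(ref, n_subs, n_dels, seed)
        diff = diff_variants(ref, query)
        assert apply_edits(ref, diff.edits) == query


@settings(derandomize=True, max_examples=80)
@given(
    st.sampled_from(["substitution", "deletion", "insertion"]),
    st.integers(1, 99),
    st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
    st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
)
def test_edit_names_parse_back_bijectively(kind, pos, aa1, aa2):
    if kind == "substitution":
        if aa1 == aa2:
            return
        edit = Edit(kind, pos, aa1, aa2)
    elif kind == "deletion":
        edit = Edit(kind, pos, ref_aa=aa1)
    else:
        edit = Edit(kind, pos, alt_aa=aa2)
    assert parse_edit_name(edit.name) == edit


class TestHinge:
    @pytest.mark.parametrize("variant,expected",
                             [("A", "NMK"), ("E", "PIK"), ("U", "PLK")])
    def test_hinge_tripeptides(self, cores, variant, expected):
        assert hinge_region(cores[variant]) == expected

    def test_deleted_hinge_position_is_an_error(self, cores):
        # remove the hinge block entirely from nisin A
        truncated = cores["A"][:19] + cores["A"][22:]
        with pytest.raises(ValueError, match="hinge"):
            hinge_region(truncated)


class TestIdentityMatrix:
    def test_a_vs_e_off_diagonal(self, peptide_records):
        pair = [p for p in peptide_records if p.id in ("A", "E")]
        m = identity_matrix(pair)
        assert m.get("A", "E") == pytest.approx(75.0)
        assert m.get("A", "A") == 100.0

    def test_a_vs_z_single_substitution(self, cores):
        m = identity_matrix([
            PeptideRecord("A", cores["A"]), PeptideRecord("Z", cores["Z"]),
        ])
        assert m.get("A", "Z") == pytest.approx(100 * 33 / 34)

    def test_e_vs_u_29_of_31(self, cores):
        m = identity_matrix([
            PeptideRecord("E", cores["E"]), PeptideRecord("U", cores["U"]),
        ])
        assert m.get("E", "U") == pytest.approx(100 * 29 / 31)

    def test_duplicate_ids_rejected(self, cores):
        with pytest.raises(ValueError, match="duplicate"):
            identity_matrix([
                PeptideRecord("x", cores["A"]), PeptideRecord("x", cores["E"]),
            ])

    def test_asymmetric_matrix_rejected(self):
        import numpy as np

        with pytest.raises(ValueError, match="symmetric"):
            IdentityMatrix(["a", "b"], np.array([[100.0, 50], [60, 100.0]]))


class TestTrees:
    def test_streptococcal_variants_pair_together(self, peptide_records):
        newick = nj_tree(identity_matrix(peptide_records))
        splits = oracles.tree_bipartitions(newick)
        assert frozenset({"A", "Z"}) in splits or frozenset({"E", "U"}) in splits

    def test_fewer_than_three_taxa_rejected(self, cores):
        m = identity_matrix([
            PeptideRecord("A", cores["A"]), PeptideRecord("E", cores["E"]),
        ])
        with pytest.raises(ValueError, match="three"):
            nj_tree(m)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nj_recovers_additive_five_taxon_topology(self, seed):
        """NJ on distances generated from a known 5-taxon tree recovers the
        generating bipartitions {a,b} and {c,d}."""
        import numpy as np

        rng = np.random.default_rng(seed)
        # tree ((a,b),(c,d),e) with random positive branch lengths
        ab, cd = rng.uniform(1, 5, 2)  # internal edges
        ta, tb, tc, td, te = rng.uniform(1, 5, 5)
        labels = ["a", "b", "c", "d", "e"]
        paths = {
            ("a", "b"): ta + tb, ("c", "d"): tc + td,
            ("a", "c"): ta + ab + cd + tc, ("a", "d"): ta + ab + cd + td,
            ("b", "c"): tb + ab + cd + tc, ("b", "d"): tb + ab + cd + td,
            ("a", "e"): ta + ab + te, ("b", "e"): tb + ab + te,
            ("c", "e"): tc + cd + te, ("d", "e"): td + cd + te,
        }
        vals = np.full((5, 5), 100.0)
        for (x, y), d in paths.items():
            i, j = labels.index(x), labels.index(y)
            vals[i, j] = vals[j, i] = 100.0 - d
        newick = nj_tree(IdentityMatrix(labels, vals))
        splits = oracles.tree_bipartitions(newick)
        assert frozenset({"a", "b"}) in splits
        assert frozenset({"c", "d"}) in splits

    def test_upgma_alternative_produces_all_taxa(self, peptide_records):
        newick = upgma_tree(identity_matrix(peptide_records))
        for p in peptide_records:
            assert p.id in newick
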