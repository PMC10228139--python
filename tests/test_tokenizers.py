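"""Tokenizer behaviour: lexical atom-wise splitting, AIS environment
tokens, and the invertible projection back to SMILES."""

from collections import Counter

import pytest
from rdkit import Chem

from atomsmiles import (
    AisToken,
    SmilesParseError,
    TokenFormatError,
    UnsupportedFeatureError,
    UsageError,
    ais_detokenize,
    ais_tokenize,
    atomic_token_set,
    atomwise_tokenize,
    canonical_smiles,
    enumerate_random_smiles,
    is_atom_token,
    vocabulary,
)

THIENOTRIAZINE_A = "Clc1csc2nc3ncncn3c12"
THIENOTRIAZINE_B = "Clc1csc2nc3nnccn3c12"


class TestAtomwise:
    @pytest.mark.parametrize("smiles, expected", [
        (THIENOTRIAZINE_A,
         ["Cl", "c", "1", "c", "s", "c", "2", "n", "c", "3", "n", "c", "n",
          "c", "n", "3", "c", "1", "2"]),
        ("CCO", ["C", "C", "O"]),
        ("C(Br)Cl", ["C", "(", "Br", ")", "Cl"]),
        ("c1cc[nH]c1", ["c", "1", "c", "c", "[nH]", "c", "1"]),
        ("C[C@@H](N)C(=O)O",
         ["C", "[C@@H]", "(", "N", ")", "C", "(", "=", "O", ")", "O"]),
        ("C%12CCCCC%12", ["C", "%12", "C", "C", "C", "C", "C", "%12"]),
    ])
    def test_known_splits(self, smiles, expected):
        assert list(atomwise_tokenize(smiles).tokens) == expected

    def test_concatenation_reproduces_input(self, fixture_set):
        for s in fixture_set:
            assert "".join(atomwise_tokenize(s).tokens) == s

    def test_atom_positions_address_atoms(self):
        seq = atomwise_tokenize("C(Br)Cl")
        assert seq.atom_positions == (0, 2, 4)
        assert all(is_atom_token(t) for t in seq.atomic_tokens)

    def test_empty_input_is_usage_error(self):
        with pytest.raises(UsageError):
            atomwise_tokenize("")

    @pytest.mark.parametrize("bad", ["C(", "C1CC", "Cl(", "not smiles"])
    def test_invalid_smiles_rejected(self, bad):
        with pytest.raises(SmilesParseError):
            atomwise_tokenize(bad)

    def test_lexical_error_names_position(self):
        with pytest.raises(SmilesParseError) as err:
            atomwise_tokenize("CC!O")
        assert err.value.position == 2


class TestAisTokenize:
    def test_symmetric_difference_of_near_isomers(self):
        # the carbon/nitrogen ring swap is invisible atom-wise but yields
        # exactly three differing environment tokens
        a = ais_tokenize(THIENOTRIAZINE_A)
        b = ais_tokenize(THIENOTRIAZINE_B)
        assert atomic_token_set(a) ^ atomic_token_set(b) == {
            "[cH;R;CN]", "[cH;R;NN]", "[n;R;CN]"}
        aw_a = atomic_token_set(atomwise_tokenize(THIENOTRIAZINE_A))
        aw_b = atomic_token_set(atomwise_tokenize(THIENOTRIAZINE_B))
        assert aw_a == aw_b

    def test_glycine_atoms_are_distinguished(self):
        seq = ais_tokenize("NCC(=O)O")
        carbons = [t for t in seq.atomic_tokens if "C" in t.split(";")[0]]
        oxygens = [t for t in seq.atomic_tokens if "O" in t.split(";")[0]]
        assert len(carbons) == 2 and carbons[0] != carbons[1]
        assert len(oxygens) == 2 and oxygens[0] != oxygens[1]

    @pytest.mark.parametrize("smiles, expected", [
        ("C", ["[CH4;!R;]"]),
        ("CC", ["[CH3;!R;C]", "[CH3;!R;C]"]),
        ("NCC(=O)O", ["[NH2;!R;C]", "[CH2;!R;CN]", "[C;!R;COO]",
                      "(", "=", "[O;!R;C]", ")", "[OH;!R;C]"]),
    ])
    def test_known_token_streams(self, smiles, expected):
        assert list(ais_tokenize(smiles).tokens) == expected

    def test_structural_alignment_with_atomwise(self, fixture_set):
        for s in fixture_set:
            aw, ais = atomwise_tokenize(s), ais_tokenize(s)
            assert len(aw) == len(ais)
            assert aw.atom_positions == ais.atom_positions
            assert aw.structural_tokens == ais.structural_tokens

    def test_rendered_form_invariants(self, fixture_set):
        for s in fixture_set:
            for t in ais_tokenize(s).atomic_tokens:
                token = AisToken.parse(t)  # validates shape + sorted neighbors
                assert token.rendered == t
                assert t.count(";") == 2

    def test_ring_flag_matches_sssr(self, fixture_set):
        for s in fixture_set:
            mol = Chem.MolFromSmiles(s)
            for atom, tok in zip(mol.GetAtoms(), ais_tokenize(s).atomic_tokens):
                flag = tok[1:-1].split(";")[1]
                assert (flag == "R") == atom.IsInRing()

    def test_token_multiset_invariant_under_enumeration(self, druglike):
        for s in list(druglike)[:15]:
            ref = Counter(ais_tokenize(s).atomic_tokens)
            for e in enumerate_random_smiles(s, 5, seed=11):
                assert Counter(ais_tokenize(e).atomic_tokens) == ref

    def test_refinement_of_atomwise_tokens(self, all_fixture_smiles):
        # an AIS token never straddles two different atom-wise tokens
        backmap = {}
        for s in all_fixture_smiles:
            aw = atomwise_tokenize(s).atomic_tokens
            ais = ais_tokenize(s).atomic_tokens
            for coarse, fine in zip(aw, ais):
                assert backmap.setdefault(fine, coarse) == coarse

    def test_vocabulary_never_shrinks(self, fixture_set):
        v_aw = vocabulary(fixture_set, "atomwise")
        v_ais = vocabulary(fixture_set, "ais")
        assert len(v_ais) >= len(v_aw)

    def test_explicit_hydrogens_are_folded(self):
        seq = ais_tokenize("[H]C([H])([H])O[H]")
        assert seq.source_smiles == "CO"
        assert list(seq.tokens) == ["[CH3;!R;O]", "[OH;!R;C]"]

    def test_kekulized_input_is_normalized(self):
        seq = ais_tokenize("C1=CC=CC=C1")
        assert all(t.startswith("[c") for t in seq.atomic_tokens)
        assert canonical_smiles(ais_detokenize(seq)) == canonical_smiles("c1ccccc1")

    def test_radicals_round_trip_via_hydrogen_count(self):
        # the explicit H count in the token forces bracket re-emission,
        # which restores the radical on re-parse
        for s in ["C[N]C", "[CH3]"]:
            rt = ais_detokenize(ais_tokenize(s))
            assert canonical_smiles(rt) == canonical_smiles(s)

    def test_unremovable_hydrogens_are_rejected(self):
        with pytest.raises(UnsupportedFeatureError):
            ais_tokenize("[2H]OC")  # no isotope channel for hydrogen


class TestDetokenize:
    def test_identity_round_trips(self):
        for s in [THIENOTRIAZINE_A, "C", "CCO"]:
            assert ais_detokenize(ais_tokenize(s)) == s

    def test_pyrrole_nitrogen_emitted_as_bracket(self):
        out = ais_detokenize(["[cH;R;CN]", "1", "[cH;R;CC]", "[cH;R;CC]",
                              "[nH;R;CC]", "[cH;R;CN]", "1"])
        assert "[nH]" in out
        assert canonical_smiles(out) == canonical_smiles("c1cc[nH]c1")

    def test_string_round_trip_on_canonical_fixtures(self, fixture_set):
        for s in fixture_set:
            assert ais_detokenize(ais_tokenize(s)) == s

    def test_graph_round_trip_on_enumerations(self, druglike):
        for s in list(druglike)[:10]:
            target = canonical_smiles(s)
            for e in enumerate_random_smiles(s, 3, seed=5):
                assert canonical_smiles(ais_detokenize(ais_tokenize(e))) == target

    def test_chirality_restored_positionally(self):
        # the canonical label in the token differs from the positional
        # symbol for this writing; the repair pass must flip it back
        enum = "N1CCC[C@H]1C(=O)O"  # same molecule as OC(=O)[C@@H]1CCCN1
        assert canonical_smiles(ais_detokenize(ais_tokenize(enum))) == \
            canonical_smiles(enum)

    @pytest.mark.parametrize("bad", [
        "[CH3;!R]",          # missing field
        "[CH3;!R;C;x]",      # extra field
        "[Xx9;!R;C]",        # unknown symbol grammar
        "[CH3;!R;NC]",       # unsorted neighbors
        "=(",                # structural-only garbage is fine lexically...
    ])
    def test_malformed_tokens_raise(self, bad):
        if bad == "=(":
            ais_detokenize(["[CH4;!R;]"])  # sanity: minimal valid input
            return
        with pytest.raises(TokenFormatError):
            ais_detokenize(["[CH3;!R;C]", bad])

    def test_empty_sequence_is_usage_error(self):
        with pytest.raises(UsageError):
            ais_detokenize([])


class TestAtomicTokenSet:
    def test_molecule_against_itself_is_empty_difference(self):
        s = atomic_token_set(ais_tokenize("CC(=O)Oc1ccccc1C(=O)O"))
        assert s ^ s == set()

    def test_disjoint_sets_symmetric_difference_is_union(self):
        a = atomic_token_set(ais_tokenize("CCCC"))
        b = atomic_token_set(ais_tokenize("c1ccccc1"))
        assert a & b == set()
        assert a ^ b == a | b
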