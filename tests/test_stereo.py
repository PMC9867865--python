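"""Stereocenter detection and stereoisomer enumeration against worked
examples and the brute-force orbit-counting oracle."""

import pytest

from molenum import build_stereo_model, enumerate_stereoisomers, parse_formula
from molenum.oracle import brute_spatial, brute_stereo
from molenum.pipeline import count_isomers, enumerate_isomers
from molenum.filters import RestrictionSet
from molenum.stereo import enumerate_true_vectors, permute_vector
from conftest import molecule


def model_of(smiles: str):
    return build_stereo_model(molecule(smiles))


class TestTrueCenterDetection:
    def test_four_distinct_substituents(self):
        model = model_of("FC(Cl)Br")
        assert model.n_tet == 1 and model.n_ct == 0

    def test_dihalide_chain_has_two_true_tet_centers(self):
        model = model_of("ClC(Br)CC(Br)Cl")
        assert model.n_tet == 2 and model.n_ct == 0

    def test_propane_center_rejected(self):
        model = model_of("CC(C)C")  # also covers three identical branches
        assert model.n_tet == 0 and not model.para_centers

    def test_conjugated_diene_has_two_cis_trans_centers(self):
        model = model_of("BrC=CC=CBr")
        assert model.n_ct == 2 and model.n_tet == 0

    def test_ethene_has_no_centers(self):
        model = model_of("C=C")
        assert not model.true_centers and not model.para_centers

    def test_butene_single_cis_trans_center(self):
        model = model_of("CC=CC")
        assert model.n_ct == 1

    def test_ring_double_bond_excluded(self):
        model = model_of("CC1=C(C)CCC1")
        assert model.n_ct == 0

    def test_para_candidate_between_true_centers(self):
        # 2,4-dichloropentan-3-ol pattern: central atom flanked by two
        # automorphism-swapped true centers
        model = model_of("CC(Cl)C(O)C(Cl)C")
        assert model.n_tet == 2
        assert len(model.para_centers) == 1


class TestConfigurationTransport:
    def test_identity_keeps_vector(self):
        model = model_of("ClC(Br)CC(Br)Cl")
        identity = tuple(range(model.graph.n_atoms))
        assert permute_vector(model, identity, model.true_centers, (0, 1)) == (0, 1)

    def test_flip_exchanges_entries_up_to_parity(self):
        # the end-to-end flip maps each vector onto its reverse (possibly
        # bit-flipped); the orbit structure must merge exactly one pair
        model = model_of("ClC(Br)CC(Br)Cl")
        vectors = enumerate_true_vectors(model)
        assert len(vectors) == 3

    def test_diene_merges_antisymmetric_pair(self):
        model = model_of("BrC=CC=CBr")
        vectors = enumerate_true_vectors(model)
        assert len(vectors) == 3
        # of the four binary vectors exactly one is equivalent to a smaller one
        assert sum(1 for v in [(0, 0), (0, 1), (1, 0), (1, 1)] if v in vectors) == 3


class TestWorkedExamples:
    def test_dihalide_meso_pattern(self):
        isomers = enumerate_stereoisomers(model_of("ClC(Br)CC(Br)Cl"))
        assert len(isomers) == 3
        by_config = {iso.true_config: iso for iso in isomers}
        # the symmetric configuration is meso (self-mirror, no enantiomer);
        # the other two form an enantiomer pair
        enantiomer_free = [iso for iso in isomers if iso.enantiomer is None]
        assert len(enantiomer_free) == 1
        paired = [iso for iso in isomers if iso.enantiomer is not None]
        assert len(paired) == 2
        a, b = paired
        assert isomers[a.enantiomer] is b and isomers[b.enantiomer] is a

    def test_diene_three_stereoisomers(self):
        isomers = enumerate_stereoisomers(model_of("BrC=CC=CBr"))
        assert len(isomers) == 3
        assert all(iso.enantiomer is None for iso in isomers)

    def test_butene_two(self):
        assert len(enumerate_stereoisomers(model_of("CC=CC"))) == 2

    def test_no_stereocenters_single_isomer(self):
        assert len(enumerate_stereoisomers(model_of("CCO"))) == 1

    def test_heptane_spatial_count(self):
        assert count_isomers("C7H16") == (9, 11)


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "smiles",
        [
            "CC(Cl)C(Cl)C(Cl)C",  # active/inactive para center
            "CC(O)C(O)C(O)C",
            "OCC(O)C(O)CO",
            "CC(C(C)Cl)C(C)Cl",
            "CC(O)C(C)C(O)C",
            "ClC=CC=CC=CCl",  # chained cis/trans
            "CC=C(Cl)C=CC",
            "OC(Cl)C(Cl)O",
            "CC(C=CC)O",  # mixed tetrahedral + cis/trans
            "ClCC(Cl)CC(Cl)CCl",
        ],
    )
    def test_single_molecule_counts(self, smiles):
        iso = molecule(smiles)
        assert len(enumerate_stereoisomers(build_stereo_model(iso))) == brute_stereo(
            iso.graph
        )

    @pytest.mark.parametrize(
        "formula",
        ["C3H4Br2", "C4H6BrCl", "C3H6O2", "C4H8O", "C5H8Cl2", "C4H7ClO"],
    )
    def test_acyclic_formula_totals(self, formula):
        (concrete,) = parse_formula(formula).expand()
        expected = brute_spatial(concrete)
        _, got = count_isomers(formula, RestrictionSet(cycles=0))
        assert got == expected


class TestInvariants:
    def test_count_bounds(self):
        for formula in ("C4H8O", "C5H8Cl2"):
            for record in enumerate_isomers(formula):
                model = build_stereo_model(record.isomer)
                n_centers = len(model.true_centers) + len(model.para_centers)
                assert 1 <= len(record.stereoisomers) <= 2 ** n_centers
                if n_centers == 0:
                    assert len(record.stereoisomers) == 1

    def test_group_closure_of_reported_vectors(self):
        model = model_of("ClC(Br)CC(Br)Cl")
        reported = {iso.true_config for iso in enumerate_stereoisomers(model)}
        for pi in model.automorphisms:
            for vec in reported:
                image = permute_vector(model, pi, model.true_centers, vec)
                assert any(
                    any(
                        permute_vector(model, q, model.true_centers, image) == r
                        for q in model.automorphisms
                    )
                    for r in reported
                )

    def test_enantiomer_is_involution(self):
        for formula in ("C5H8Cl2", "C4H7ClO"):
            for record in enumerate_isomers(formula):
                for idx, iso in enumerate(record.stereoisomers):
                    if iso.enantiomer is not None:
                        partner = record.stereoisomers[iso.enantiomer]
                        assert partner.enantiomer == idx
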