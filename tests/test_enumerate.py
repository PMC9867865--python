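"""Orderly generation: hydrogen distribution, canonical matrices and the
automorphism groups they carry."""

import itertools

import pytest

from molenum import (
    UnitedAtom,
    apply_permutation,
    distribute_hydrogens,
    enumerate_canonical_matrices,
    lex_compare,
    parse_formula,
)
from molenum.oracle import brute_formula


def concrete(text: str):
    (c,) = list(parse_formula(text).expand())
    return c


def all_isomers(text: str, max_order: int = 3):
    out = []
    for partition in distribute_hydrogens(concrete(text)):
        out.extend(enumerate_canonical_matrices(partition, max_order))
    return out


class TestDistributeHydrogens:
    def test_ethane_single_partition(self):
        parts = distribute_hydrogens(concrete("C2H6"))
        assert parts == [(UnitedAtom.of("C", 3), UnitedAtom.of("C", 3))]

    def test_pinned_partition(self):
        parts = distribute_hydrogens(concrete("{CH1}1{CH2}2{OH1}3"))
        assert len(parts) == 1
        assert sorted((a.element, a.n_h) for a in parts[0]) == [
            ("C", 1),
            ("C", 2),
            ("C", 2),
            ("O", 1),
            ("O", 1),
            ("O", 1),
        ]

    def test_single_united_atom(self):
        parts = distribute_hydrogens(concrete("CH4"))
        assert parts == [(UnitedAtom("C", 4, 0),)]

    def test_impossible_distribution_is_empty(self):
        assert distribute_hydrogens(concrete("C2H2O4")) != []  # sanity: feasible
        assert distribute_hydrogens(concrete("CH2Cl2")) == [
            (UnitedAtom.of("C", 2), UnitedAtom.of("Cl"), UnitedAtom.of("Cl"))
        ]

    def test_exhaustive_assignment_oracle(self):
        # independently distribute H over labeled atoms and collapse
        c = concrete("C3H8O")
        heavy = ["C", "C", "C", "O"]
        expected = set()
        for combo in itertools.product(range(4), range(4), range(4), range(2)):
            if sum(combo) != 8:
                continue
            atoms = tuple(
                sorted(
                    (UnitedAtom.of(e, h) for e, h in zip(heavy, combo)),
                    key=lambda a: (a.element, a.n_h),
                )
            )
            if all(a.valence >= 1 for a in atoms):
                total = sum(a.valence for a in atoms)
                if total % 2 == 0 and total >= 2 * (len(atoms) - 1):
                    expected.add(atoms)
        got = {
            tuple(sorted(p, key=lambda a: (a.element, a.n_h)))
            for p in distribute_hydrogens(c)
        }
        assert got == expected


class TestCanonicalEnumeration:
    @pytest.mark.parametrize(
        "formula, expected",
        [("C4H10", 2), ("C10H22", 75), ("C2H6O", 2), ("C6H14", 5), ("H2", 1)],
    )
    def test_known_counts(self, formula, expected):
        assert len(all_isomers(formula)) == expected

    @pytest.mark.parametrize(
        "formula",
        ["C4H8O", "C3H9N", "C3H4O2", "C2H7N", "C4H6", "C5H12", "C3H6O2", "C2H4N2"],
    )
    def test_brute_force_oracle_equivalence(self, formula):
        expected = len(brute_formula(concrete(formula)))
        assert len(all_isomers(formula)) == expected

    def test_emissions_strictly_decreasing(self):
        for partition in distribute_hydrogens(concrete("C6H12")):
            previous = None
            for iso in enumerate_canonical_matrices(partition):
                if previous is not None:
                    assert lex_compare(previous, iso.graph.adjacency) == 1
                previous = iso.graph.adjacency

    def test_row_sums_equal_effective_valences(self):
        for iso in all_isomers("C4H8O"):
            for i, atom in enumerate(iso.graph.atoms):
                assert sum(iso.graph.adjacency[i]) == atom.valence

    def test_canonicity_by_exhaustive_permutation(self):
        checked = 0
        for formula in ("C5H8", "C4H9N", "C3H6O2", "C4H6O"):
            for iso in all_isomers(formula):
                a = iso.graph.adjacency
                blocks = [list(b) for b in iso.graph.partitions]
                for pieces in itertools.product(
                    *(itertools.permutations(b) for b in blocks)
                ):
                    pi = [0] * len(a)
                    for block, piece in zip(blocks, pieces):
                        for src, dst in zip(block, piece):
                            pi[src] = dst
                    assert lex_compare(apply_permutation(a, pi), a) <= 0
                checked += 1
        assert checked > 100


class TestAutomorphismGroups:
    def test_single_atom(self):
        (iso,) = all_isomers("CH4")
        assert iso.automorphisms == ((0,),)

    def test_ethane_swap_symmetry(self):
        (iso,) = all_isomers("C2H6")
        assert sorted(iso.automorphisms) == [(0, 1), (1, 0)]

    def test_n_pentane_end_to_end_flip(self):
        from conftest import molecule

        iso = molecule("CCCCC")
        exhaustive = _brute_automorphisms(iso.graph)
        assert len(exhaustive) == 2
        assert sorted(iso.automorphisms) == sorted(exhaustive)

    @pytest.mark.parametrize("formula", ["C5H12", "C4H8O", "C3H4O2"])
    def test_groups_match_exhaustive_search_and_are_closed(self, formula):
        for iso in all_isomers(formula):
            group = set(iso.automorphisms)
            assert tuple(range(iso.graph.n_atoms)) in group
            assert group == set(_brute_automorphisms(iso.graph))
            for p in group:
                inv = [0] * len(p)
                for i, v in enumerate(p):
                    inv[v] = i
                assert tuple(inv) in group
                for q in group:
                    assert tuple(q[p[i]] for i in range(len(p))) in group


def _brute_automorphisms(graph):
    out = []
    blocks = [list(b) for b in graph.partitions]
    for pieces in itertools.product(*(itertools.permutations(b) for b in blocks)):
        pi = [0] * graph.n_atoms
        for block, piece in zip(blocks, pieces):
            for src, dst in zip(block, piece):
                pi[src] = dst
        if apply_permutation(graph.adjacency, pi) == graph.adjacency:
            out.append(tuple(pi))
    return out
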