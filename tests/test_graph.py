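"""Matrix primitives: lexicographic order, permutations, connectivity,
unsaturations and cycle counts."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from molenum import (
    apply_permutation,
    cycle_count,
    is_connected,
    lex_compare,
    parse_smiles,
    unsaturations,
)


def sym_matrix(n, rng_entries):
    """Build a symmetric zero-diagonal matrix from an upper-triangle list."""
    a = [[0] * n for _ in range(n)]
    it = iter(rng_entries)
    for i in range(n):
        for j in range(i + 1, n):
            a[i][j] = a[j][i] = next(it)
    return tuple(tuple(r) for r in a)


def upper(a):
    n = len(a)
    return tuple(a[i][j] for i in range(n) for j in range(i + 1, n))


matrices5 = st.lists(st.integers(0, 3), min_size=10, max_size=10).map(
    lambda e: sym_matrix(5, e)
)


class TestLexCompare:
    def test_equal_to_itself(self):
        a = sym_matrix(3, [1, 0, 2])
        assert lex_compare(a, a) == 0

    def test_first_difference_decides(self):
        a = sym_matrix(3, [1, 0, 0])
        b = sym_matrix(3, [0, 1, 0])
        assert lex_compare(a, b) == 1
        assert lex_compare(b, a) == -1

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            lex_compare(sym_matrix(3, [0] * 3), sym_matrix(4, [0] * 6))

    @settings(derandomize=True, max_examples=100)
    @given(matrices5, matrices5)
    def test_matches_flattened_tuple_comparison(self, a, b):
        expected = (upper(a) > upper(b)) - (upper(a) < upper(b))
        assert lex_compare(a, b) == expected

    @settings(derandomize=True, max_examples=50)
    @given(matrices5, matrices5, matrices5)
    def test_total_order(self, a, b, c):
        assert lex_compare(a, b) == -lex_compare(b, a)
        if lex_compare(a, b) >= 0 and lex_compare(b, c) >= 0:
            assert lex_compare(a, c) >= 0


class TestApplyPermutation:
    def test_identity(self):
        a = sym_matrix(4, [1, 0, 2, 1, 0, 3])
        assert apply_permutation(a, (0, 1, 2, 3)) == a

    def test_inverse_round_trip(self):
        a = sym_matrix(4, [1, 0, 2, 1, 0, 3])
        perm = (2, 0, 3, 1)
        inv = [0] * 4
        for i, p in enumerate(perm):
            inv[p] = i
        assert apply_permutation(apply_permutation(a, perm), tuple(inv)) == a

    def test_rejects_non_bijection(self):
        with pytest.raises(ValueError):
            apply_permutation(sym_matrix(3, [1, 0, 0]), (0, 0, 1))

    @settings(derandomize=True, max_examples=50)
    @given(matrices5, st.permutations(range(5)), st.permutations(range(5)))
    def test_group_action_composition(self, a, p, q):
        compose = tuple(q[p[i]] for i in range(5))
        assert apply_permutation(apply_permutation(a, p), q) == apply_permutation(
            a, compose
        )

    @settings(derandomize=True, max_examples=50)
    @given(matrices5, st.permutations(range(5)))
    def test_row_sum_multiset_preserved(self, a, p):
        b = apply_permutation(a, p)
        assert sorted(map(sum, a)) == sorted(map(sum, b))

    def test_automorphism_fixes_matrix(self):
        from conftest import molecule

        iso = molecule("CC(C)C")
        for pi in iso.automorphisms:
            assert apply_permutation(iso.graph.adjacency, pi) == iso.graph.adjacency


class TestConnectivity:
    def test_single_atom(self):
        assert is_connected(((0,),))

    def test_two_unbonded_atoms(self):
        assert not is_connected(((0, 0), (0, 0)))

    def test_two_disjoint_pairs(self):
        a = sym_matrix(4, [1, 0, 0, 0, 0, 1])
        assert not is_connected(a)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(2, 10), st.data())
    def test_matches_union_find(self, n, data):
        entries = data.draw(
            st.lists(st.integers(0, 1), min_size=n * (n - 1) // 2, max_size=n * (n - 1) // 2)
        )
        a = sym_matrix(n, entries)
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if a[i][j]:
                    parent[find(i)] = find(j)
        assert is_connected(a) == (len({find(i) for i in range(n)}) == 1)


class TestUnsaturations:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"C": 1, "H": 4}, 0),
            ({"C": 2, "H": 4}, 1),
            ({"C": 5, "H": 8, "Br": 2}, 1),
            ({"C": 6, "H": 6}, 4),
            ({"C": 2, "H": 6, "O": 1}, 0),
        ],
    )
    def test_closed_form(self, counts, expected):
        assert unsaturations(counts) == expected

    def test_odd_valence_sum_rejected(self):
        with pytest.raises(ValueError):
            unsaturations({"C": 1, "H": 3})

    def test_equals_rings_plus_multiple_bonds_on_enumerated_isomers(self):
        from molenum import enumerate_isomers

        for record in enumerate_isomers("C4H6", stereo=False):
            graph = record.isomer.graph
            extra = sum(order - 1 for _, _, order in graph.bonds())
            assert cycle_count(graph) + extra == unsaturations(graph.formula())


class TestCycleCount:
    @pytest.mark.parametrize(
        "smiles, expected",
        [("CCCC", 0), ("C1CCCCC1", 1), ("C1CC1", 1), ("C12CC1C2", 2), ("C=C", 0)],
    )
    def test_cyclomatic_number(self, smiles, expected):
        assert cycle_count(parse_smiles(smiles)) == expected

    def test_disconnected_rejected(self):
        from molenum import MolecularGraph, UnitedAtom

        atoms = (UnitedAtom.of("C", 3), UnitedAtom.of("C", 3))
        with pytest.raises(ValueError):
            cycle_count(MolecularGraph(atoms, ((0, 0), (0, 0))))
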