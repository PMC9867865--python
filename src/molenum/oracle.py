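"""Brute-force reference enumerators for small molecules.

These are deliberately naive, independent re-derivations used by the test
suite to certify the optimized enumerator on small instances.  They share
no logic with the orderly generator: duplicates are removed with VF2 graph
isomorphism (networkx), hydrogens are distributed over *labeled* atoms, and
stereoisomers are counted as orbits of parity assignments under the full
automorphism group.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import networkx as nx

from .formula import ConcreteFormula
from .graph import VALENCES, MolecularGraph, UnitedAtom

__all__ = ["brute_constitutional", "brute_formula", "brute_stereo", "brute_spatial"]

_MAX_ATOMS = 8
_MAX_STEREO_ATOMS = 10


def _all_matrices(valences: Sequence[int], max_order: int):
    """Every symmetric matrix with the given row sums (upper triangle DFS)."""
    n = len(valences)
    a = [[0] * n for _ in range(n)]
    rem = list(valences)
    cells = [(i, j) for i in range(n) for j in range(i + 1, n)]

    def fill(k: int):
        if k == len(cells):
            if all(r == 0 for r in rem):
                yield tuple(tuple(row) for row in a)
            return
        i, j = cells[k]
        for v in range(min(rem[i], rem[j], max_order) + 1):
            a[i][j] = a[j][i] = v
            rem[i] -= v
            rem[j] -= v
            yield from fill(k + 1)
            rem[i] += v
            rem[j] += v
        a[i][j] = a[j][i] = 0

    yield from fill(0)


def _to_nx(graph: MolecularGraph) -> nx.Graph:
    g = nx.Graph()
    for i, atom in enumerate(graph.atoms):
        g.add_node(i, kind=(atom.element, atom.n_h))
    for i, j, order in graph.bonds():
        g.add_edge(i, j, order=order)
    return g


def _isomorphic(g1: nx.Graph, g2: nx.Graph) -> bool:
    return nx.is_isomorphic(
        g1,
        g2,
        node_match=lambda a, b: a["kind"] == b["kind"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )


def brute_constitutional(
    atoms: Sequence[UnitedAtom], max_order: int = 3
) -> list[MolecularGraph]:
    """Isomorphism-class representatives for a fixed united-atom multiset."""
    if len(atoms) > _MAX_ATOMS:
        raise ValueError("brute-force enumeration is capped at 8 united atoms")
    atoms = tuple(atoms)
    reps: list[MolecularGraph] = []
    reps_nx: list[nx.Graph] = []
    for matrix in _all_matrices([a.valence for a in atoms], max_order):
        if not _bf_connected(matrix):
            continue
        graph = MolecularGraph(atoms, matrix)
        g = _to_nx(graph)
        if any(_isomorphic(g, r) for r in reps_nx):
            continue
        reps.append(graph)
        reps_nx.append(g)
    return reps


def brute_formula(concrete: ConcreteFormula, max_order: int = 3) -> list[MolecularGraph]:
    """All constitutional isomers of a concrete formula.

    Hydrogens are assigned to *labeled* heavy atoms by explicit composition
    (independent of the multiset-based distribution in the enumerator); the
    resulting graphs are pooled and deduplicated by isomorphism.
    """
    counts = dict(concrete.counts)
    n_h = counts.pop("H", 0)
    heavy: list[str] = []
    for element, c in sorted(counts.items()):
        heavy.extend([element] * c)
    if len(heavy) > _MAX_ATOMS:
        raise ValueError("brute-force enumeration is capped at 8 heavy atoms")
    if not heavy:
        if n_h == 2:
            h = UnitedAtom.of("H")
            return [MolecularGraph((h, h), ((0, 1), (1, 0)))]
        return []
    max_h = [VALENCES[e] - (0 if len(heavy) == 1 else 1) for e in heavy]
    reps: list[MolecularGraph] = []
    reps_nx: list[nx.Graph] = []
    seen_multisets: set = set()
    for combo in itertools.product(*(range(m + 1) for m in max_h)):
        if sum(combo) != n_h:
            continue
        atoms = tuple(UnitedAtom.of(e, h) for e, h in zip(heavy, combo))
        key = tuple(sorted(atoms))
        if key in seen_multisets:
            continue  # a permutation of an already-processed labeled assignment
        seen_multisets.add(key)
        for graph in brute_constitutional(atoms, max_order):
            g = _to_nx(graph)
            if any(_isomorphic(g, r) for r in reps_nx):
                continue
            reps.append(graph)
            reps_nx.append(g)
    return reps


def _bf_connected(matrix) -> bool:
    n = len(matrix)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in range(n):
            if matrix[u][v] and v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == n


# ---------------------------------------------------------------------------
# stereo


def _automorphisms(graph: MolecularGraph) -> list[tuple[int, ...]]:
    """All type-preserving matrix-fixing permutations, by exhaustion."""
    n = graph.n_atoms
    blocks: dict = {}
    for i, atom in enumerate(graph.atoms):
        blocks.setdefault(atom, []).append(i)
    block_lists = list(blocks.values())
    a = graph.adjacency
    out = []
    for pieces in itertools.product(
        *(itertools.permutations(b) for b in block_lists)
    ):
        pi = [0] * n
        for block, piece in zip(block_lists, pieces):
            for src, dst in zip(block, piece):
                pi[src] = dst
        if all(
            a[i][j] == a[pi[i]][pi[j]] for i in range(n) for j in range(i + 1, n)
        ):
            out.append(tuple(pi))
    return out


def _parity(perm: Sequence[int]) -> int:
    seen = [False] * len(perm)
    p = 0
    for i in range(len(perm)):
        j, length = i, 0
        while not seen[j]:
            seen[j] = True
            j = perm[j]
            length += 1
        if length:
            p ^= (length - 1) & 1
    return p


def brute_stereo(graph: MolecularGraph, count_only: bool = True) -> int:
    """Number of stereoisomers of an acyclic molecule, by orbit counting.

    Every atom with four singly-bonded substituents (at most one implicit
    hydrogen) and every eligible double bond receives a parity bit; two
    assignments describe the same stereoisomer when some automorphism maps
    one onto the other, flipping a tetrahedral bit for an odd permutation
    of the neighbor tuple and a double-bond bit when exactly one reference
    neighbor fails to map onto the image's reference neighbor.
    """
    if graph.n_atoms > _MAX_STEREO_ATOMS:
        raise ValueError("brute-force stereo counting is capped at 10 united atoms")
    bonds = graph.bonds()
    if len(bonds) >= graph.n_atoms and graph.n_atoms > 1:
        raise ValueError("brute-force stereo counting handles acyclic molecules")
    adj = graph.adjacency
    atoms = graph.atoms

    def single_neighbors(i: int) -> list[int]:
        return [j for j in graph.neighbors(i) if adj[i][j] == 1]

    tet = [
        i
        for i in range(graph.n_atoms)
        if atoms[i].full_valence == 4
        and atoms[i].n_h <= 1
        and len(single_neighbors(i)) == atoms[i].valence  # all bonds single
        and atoms[i].valence + atoms[i].n_h == 4
    ]
    ct = []
    for i, j, order in bonds:
        if order != 2:
            continue
        if all(
            atoms[k].full_valence == 4
            and atoms[k].n_h <= 1
            and len(single_neighbors(k)) + atoms[k].n_h == 2
            and sum(1 for x in graph.neighbors(k) if adj[k][x] == 2) == 1
            for k in (i, j)
        ):
            ct.append((i, j))

    auts = _automorphisms(graph)
    ref = {i: min(single_neighbors(i)) for i, j in ct} | {
        j: min(single_neighbors(j)) for i, j in ct
    }

    def transport(pi, assignment):
        out_tet = {}
        for i, bit in assignment[0].items():
            src = sorted(graph.neighbors(i))
            dst = sorted(graph.neighbors(pi[i]))
            perm = [dst.index(pi[x]) for x in src]
            out_tet[pi[i]] = bit ^ _parity(perm)
        out_ct = {}
        for (i, j), bit in assignment[1].items():
            a2, b2 = pi[i], pi[j]
            flip = (pi[ref[i]] != ref[a2]) ^ (pi[ref[j]] != ref[b2])
            key = (a2, b2) if a2 < b2 else (b2, a2)
            out_ct[key] = bit ^ (1 if flip else 0)
        return out_tet, out_ct

    def freeze(assignment):
        return (
            tuple(sorted(assignment[0].items())),
            tuple(sorted(assignment[1].items())),
        )

    classes = set()
    for tet_bits in itertools.product((0, 1), repeat=len(tet)):
        for ct_bits in itertools.product((0, 1), repeat=len(ct)):
            assignment = (
                dict(zip(tet, tet_bits)),
                dict(zip(ct, ct_bits)),
            )
            canonical = min(freeze(transport(pi, assignment)) for pi in auts)
            classes.add(canonical)
    return len(classes)


def brute_spatial(concrete: ConcreteFormula, max_order: int = 3) -> int:
    """Total spatial isomer count over the acyclic skeletons of a formula."""
    total = 0
    for graph in brute_formula(concrete, max_order):
        if len(graph.bonds()) == graph.n_atoms - 1:  # tree skeleton
            total += brute_stereo(graph)
    return total
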