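"""Property restrictions, substructure counting and Kekulé deduplication.

Restrictions are count sets over molecular properties (unsaturations, bond
tallies, cycle count).  The unsaturation restriction prunes whole formulas
before any matrix is generated; the others are evaluated per emitted
isomer.  Substructures are counted with subgraph monomorphisms under the
convention that accepted matches may pairwise share at most one atom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .graph import MolecularGraph, UnitedAtom, cycle_count
from .smiles import canonical_key

__all__ = [
    "RestrictionSet",
    "Substructure",
    "passes_filters",
    "count_substructure",
    "aromatic_dedup",
]

CountSet = frozenset[int] | None


def _as_count_set(value) -> CountSet:
    if value is None:
        return None
    if isinstance(value, int):
        return frozenset((value,))
    if isinstance(value, range):
        return frozenset(value)
    return frozenset(int(v) for v in value)


@dataclass(frozen=True)
class RestrictionSet:
    """Admissible values for molecular properties; ``None`` = unrestricted."""

    unsaturations: CountSet = None
    total_bonds: CountSet = None
    single_bonds: CountSet = None
    double_bonds: CountSet = None
    triple_bonds: CountSet = None
    quadruple_bonds: CountSet = None
    cycles: CountSet = None
    max_bond_order: int = 3

    def __post_init__(self):
        for name in (
            "unsaturations",
            "total_bonds",
            "single_bonds",
            "double_bonds",
            "triple_bonds",
            "quadruple_bonds",
            "cycles",
        ):
            object.__setattr__(self, name, _as_count_set(getattr(self, name)))
        if not 1 <= self.max_bond_order <= 4:
            raise ValueError("max bond order must be in 1..4")

    def admits_unsaturations(self, value: int) -> bool:
        return self.unsaturations is None or value in self.unsaturations


def passes_filters(graph: MolecularGraph, restrictions: RestrictionSet) -> bool:
    """Per-isomer property filter (bond tallies and cycle count)."""
    r = restrictions
    if (
        r.total_bonds is None
        and r.single_bonds is None
        and r.double_bonds is None
        and r.triple_bonds is None
        and r.quadruple_bonds is None
        and r.cycles is None
    ):
        return True
    counts = graph.bond_order_counts()
    checks = (
        (r.total_bonds, sum(counts.values())),
        (r.single_bonds, counts.get(1, 0)),
        (r.double_bonds, counts.get(2, 0)),
        (r.triple_bonds, counts.get(3, 0)),
        (r.quadruple_bonds, counts.get(4, 0)),
        (r.cycles, cycle_count(graph)),
    )
    return all(allowed is None or value in allowed for allowed, value in checks)


# ---------------------------------------------------------------------------
# substructures


@dataclass(frozen=True)
class Substructure:
    """A pattern: named atom list plus the upper triangle of its adjacency
    matrix written row-wise ("adjacency matrix stack").

    Pattern atoms are element symbols, ``(element, n_h)`` pairs that match
    only united atoms with exactly that attached-H count, or the wildcard
    ``"*"``.  Bond orders must match exactly.
    """

    name: str
    atoms: tuple
    stack: tuple[int, ...]
    occurrences: CountSet = None

    def __post_init__(self):
        n = len(self.atoms)
        if n == 0:
            raise ValueError("substructure needs at least one atom")
        if len(self.stack) != n * (n - 1) // 2:
            raise ValueError("adjacency stack length must be n(n-1)/2")
        object.__setattr__(self, "occurrences", _as_count_set(self.occurrences))

    def matrix(self) -> list[list[int]]:
        n = len(self.atoms)
        a = [[0] * n for _ in range(n)]
        it = iter(self.stack)
        for i in range(n):
            for j in range(i + 1, n):
                a[i][j] = a[j][i] = next(it)
        return a

    @classmethod
    def from_smiles(cls, name: str, smiles: str, occurrences=None) -> "Substructure":
        from .parse import parse_pattern

        atoms, matrix = parse_pattern(smiles)
        n = len(atoms)
        stack = tuple(matrix[i][j] for i in range(n) for j in range(i + 1, n))
        return cls(name, tuple(atoms), stack, occurrences)


def _pattern_node_match(pattern_attr, atom: UnitedAtom) -> bool:
    if pattern_attr == "*":
        return True
    if isinstance(pattern_attr, str):
        return atom.element == pattern_attr
    element, n_h = pattern_attr
    return atom.element == element and atom.n_h == n_h


def _to_nx(graph: MolecularGraph) -> nx.Graph:
    g = nx.Graph()
    for i, atom in enumerate(graph.atoms):
        g.add_node(i, atom=atom)
    for i, j, order in graph.bonds():
        g.add_edge(i, j, order=order)
    return g


def count_substructure(graph: MolecularGraph, sub: Substructure) -> int:
    """Number of accepted matches under the one-atom-overlap convention.

    All monomorphic embeddings are collected as atom-set/bond-set matches
    (automorphic images counted once), sorted by their matched index
    tuples, and accepted greedily while sharing at most one atom with every
    previously accepted match.
    """
    host = _to_nx(graph)
    pat = nx.Graph()
    for k, attr in enumerate(sub.atoms):
        pat.add_node(k, spec=attr)
    m = sub.matrix()
    for i in range(len(sub.atoms)):
        for j in range(i + 1, len(sub.atoms)):
            if m[i][j]:
                pat.add_edge(i, j, order=m[i][j])
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        host,
        pat,
        node_match=lambda h, p: _pattern_node_match(p["spec"], h["atom"]),
        edge_match=lambda h, p: h["order"] == p["order"],
    )
    matches: set[tuple[frozenset, frozenset]] = set()
    for mapping in matcher.subgraph_monomorphisms_iter():
        atoms = frozenset(mapping)
        bonds = frozenset(
            frozenset((u, v))
            for u, v in itertools.combinations(mapping, 2)
            if pat.has_edge(mapping[u], mapping[v])
        )
        matches.add((atoms, bonds))
    accepted: list[frozenset] = []
    for atoms, _ in sorted(matches, key=lambda m: tuple(sorted(m[0]))):
        if all(len(atoms & prev) <= 1 for prev in accepted):
            accepted.append(atoms)
    return len(accepted)


# ---------------------------------------------------------------------------
# aromaticity


def _alternating_hexagons(graph: MolecularGraph) -> list[tuple[int, ...]]:
    """Six-membered rings whose bond orders alternate single/double."""
    g = _to_nx(graph)
    out = []
    seen: set[frozenset] = set()
    for cycle in nx.simple_cycles(g, length_bound=6):
        if len(cycle) != 6 or frozenset(cycle) in seen:
            continue
        orders = [
            graph.adjacency[cycle[k]][cycle[(k + 1) % 6]] for k in range(6)
        ]
        if sorted(orders[0::2]) == [1, 1, 1] and sorted(orders[1::2]) == [2, 2, 2]:
            seen.add(frozenset(cycle))
            out.append(tuple(cycle))
        elif sorted(orders[0::2]) == [2, 2, 2] and sorted(orders[1::2]) == [1, 1, 1]:
            seen.add(frozenset(cycle))
            out.append(tuple(cycle))
    return out


def aromatic_key(graph: MolecularGraph):
    """Canonical key with alternating 6-rings marked as aromatic, or None
    when the molecule has no such ring."""
    hexagons = _alternating_hexagons(graph)
    if not hexagons:
        return None
    a = [list(row) for row in graph.adjacency]
    for cycle in hexagons:
        for k in range(6):
            i, j = cycle[k], cycle[(k + 1) % 6]
            a[i][j] = a[j][i] = 5  # aromatic marker order
    marked = MolecularGraph(graph.atoms, tuple(tuple(r) for r in a))
    return canonical_key(marked)


def aromatic_dedup(graphs: Iterable) -> Iterable:
    """Drop Kekulé duplicates: isomers identical up to the rotation of the
    alternating bonds around six-membered aromatic rings."""
    seen: set = set()
    for item in graphs:
        graph = item.graph if hasattr(item, "graph") else item
        key = aromatic_key(graph)
        if key is not None:
            if key in seen:
                continue
            seen.add(key)
        yield item
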