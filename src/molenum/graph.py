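"""Labeled molecular multigraphs and the primitive matrix operations.

A molecule is represented as a *united-atom* multigraph: every heavy atom
absorbs its bonded hydrogens and its valence is reduced accordingly.  The
connectivity is stored as a symmetric adjacency matrix of small integer bond
orders (0 = no bond, 1..4 = single..quadruple).  Atoms of identical united
type (element + attached-H count) are interchangeable, which is what makes
canonical labeling and automorphism groups meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "VALENCES",
    "UnitedAtom",
    "MolecularGraph",
    "lex_compare",
    "apply_permutation",
    "is_connected",
    "unsaturations",
    "cycle_count",
    "atom_sort_key",
]

#: Fixed valences of the supported element types.
VALENCES: dict[str, int] = {
    "C": 4,
    "Si": 4,
    "N": 3,
    "B": 3,
    "O": 2,
    "H": 1,
    "F": 1,
    "Cl": 1,
    "Br": 1,
    "I": 1,
}

Matrix = Sequence[Sequence[int]]


@dataclass(frozen=True, order=True)
class UnitedAtom:
    """A heavy atom with its hydrogens absorbed.

    ``valence`` is the *effective* valence, i.e. the element valence minus
    the number of attached hydrogens; it equals the row sum of the adjacency
    matrix for a completed molecule.
    """

    element: str
    n_h: int
    valence: int

    @classmethod
    def of(cls, element: str, n_h: int = 0) -> "UnitedAtom":
        try:
            delta = VALENCES[element]
        except KeyError:
            raise ValueError(f"unknown element {element!r}") from None
        if n_h < 0 or n_h > delta:
            raise ValueError(f"{element} cannot carry {n_h} hydrogens")
        return cls(element, n_h, delta - n_h)

    @property
    def full_valence(self) -> int:
        return self.valence + self.n_h

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.element}H{self.n_h}" if self.n_h else self.element


def atom_sort_key(atom: UnitedAtom) -> tuple:
    """Canonical ordering of united-atom types.

    Decreasing effective valence, ties broken by element symbol, then by
    decreasing attached-H count.  Any fixed total order would do -- it only
    decides which of the equivalent matrices is "the" canonical one.
    """
    return (-atom.valence, atom.element, -atom.n_h)


@dataclass(frozen=True)
class MolecularGraph:
    """A connected united-atom multigraph with a symmetric adjacency matrix."""

    atoms: tuple[UnitedAtom, ...]
    adjacency: tuple[tuple[int, ...], ...]
    partitions: tuple[tuple[int, ...], ...] = field(default=())

    def __post_init__(self):
        n = len(self.atoms)
        if len(self.adjacency) != n or any(len(r) != n for r in self.adjacency):
            raise ValueError("adjacency matrix shape does not match atom count")
        if not self.partitions:
            object.__setattr__(self, "partitions", _type_blocks(self.atoms))

    @classmethod
    def from_lists(cls, atoms: Iterable[UnitedAtom], matrix: Matrix) -> "MolecularGraph":
        return cls(tuple(atoms), tuple(tuple(int(x) for x in row) for row in matrix))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[int]:
        return [j for j, order in enumerate(self.adjacency[i]) if order]

    def degree(self, i: int) -> int:
        """Bond-order sum of atom *i* (equals effective valence when complete)."""
        return sum(self.adjacency[i])

    def bonds(self) -> list[tuple[int, int, int]]:
        """All bonded pairs ``(i, j, order)`` with ``i < j``."""
        a = self.adjacency
        return [
            (i, j, a[i][j])
            for i in range(self.n_atoms)
            for j in range(i + 1, self.n_atoms)
            if a[i][j]
        ]

    def bond_order_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for _, _, order in self.bonds():
            counts[order] = counts.get(order, 0) + 1
        return counts

    def formula(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for atom in self.atoms:
            counts[atom.element] = counts.get(atom.element, 0) + 1
            if atom.n_h:
                counts["H"] = counts.get("H", 0) + atom.n_h
        return counts

    def relabeled(self, perm: Sequence[int]) -> "MolecularGraph":
        """Graph with atom *i* moved to position ``perm[i]``."""
        n = self.n_atoms
        atoms = [None] * n
        for i, atom in enumerate(self.atoms):
            atoms[perm[i]] = atom
        return MolecularGraph(tuple(atoms), apply_permutation(self.adjacency, perm))


def _type_blocks(atoms: Sequence[UnitedAtom]) -> tuple[tuple[int, ...], ...]:
    blocks: list[list[int]] = []
    for i, atom in enumerate(atoms):
        if blocks and atoms[blocks[-1][-1]] == atom:
            blocks[-1].append(i)
        else:
            blocks.append([i])
    # merge non-adjacent equal types defensively (atoms should be pre-sorted)
    merged: dict[UnitedAtom, list[int]] = {}
    for block in blocks:
        merged.setdefault(atoms[block[0]], []).extend(block)
    return tuple(tuple(v) for v in merged.values())


def lex_compare(a: Matrix, b: Matrix) -> int:
    """Row-wise upper-triangle comparison; the first difference decides.

    Returns -1, 0 or +1 when *a* is lexicographically smaller than, equal to
    or larger than *b*.
    """
    n = len(a)
    if len(b) != n:
        raise ValueError("matrices must have identical dimensions")
    for i in range(n):
        ra, rb = a[i], b[i]
        for j in range(i + 1, n):
            if ra[j] != rb[j]:
                return 1 if ra[j] > rb[j] else -1
    return 0


def apply_permutation(a: Matrix, perm: Sequence[int]) -> tuple[tuple[int, ...], ...]:
    """Relabel the matrix: ``result[perm[i]][perm[j]] = a[i][j]``."""
    n = len(a)
    if sorted(perm) != list(range(n)):
        raise ValueError("permutation is not a bijection on the atom indices")
    out = [[0] * n for _ in range(n)]
    for i in range(n):
        pi = perm[i]
        row = a[i]
        orow = out[pi]
        for j in range(n):
            orow[perm[j]] = row[j]
    return tuple(tuple(r) for r in out)


def is_connected(a: Matrix) -> bool:
    """Depth-first reachability from vertex 0 using an explicit LIFO stack."""
    n = len(a)
    if n == 0:
        return False
    seen = [False] * n
    seen[0] = True
    stack = [0]
    count = 1
    while stack:
        i = stack.pop()
        row = a[i]
        for j in range(n):
            if row[j] and not seen[j]:
                seen[j] = True
                count += 1
                stack.append(j)
    return count == n


def unsaturations(counts: dict[str, int]) -> int:
    """Degree of unsaturation of a molecular formula.

    Closed form ``(2 + sum_e n_e (delta_e - 2)) / 2`` for fixed valences:
    one per ring or double bond, two per triple bond.  A negative value
    means the formula admits no molecule.
    """
    total = 2
    n_atoms = 0
    for element, n in counts.items():
        if n < 0:
            raise ValueError("negative atom count")
        try:
            delta = VALENCES[element]
        except KeyError:
            raise ValueError(f"unknown element {element!r}") from None
        total += n * (delta - 2)
        n_atoms += n
    if n_atoms == 0:
        raise ValueError("empty formula")
    if total % 2:
        raise ValueError("odd valence sum: formula is not closed-shell")
    return total // 2


def cycle_count(graph: MolecularGraph) -> int:
    """Cyclomatic number ``E - N + 1`` of the simple-graph skeleton.

    Bond multiplicity is ignored: a double bond is an unsaturation but not a
    cycle.  Requires a connected graph.
    """
    if not is_connected(graph.adjacency):
        raise ValueError("cycle count is defined for connected graphs only")
    return len(graph.bonds()) - graph.n_atoms + 1
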