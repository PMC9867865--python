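"""Deterministic canonical SMILES generation.

The atom ranking starts from local invariants (element, attached-H count,
effective valence, degree, bond-order multiset) and is refined by the
sorted ranks of each atom's neighbors until stable.  Remaining ties are
resolved by individualizing each tied candidate in turn, re-refining, and
keeping the labeling whose relabeled adjacency matrix is smallest -- this
makes the labeling canonical (identical molecules under any input atom
numbering receive identical strings), not merely deterministic.

Stereo annotations are written relative to the string itself: tetrahedral
configuration 0 maps to ``@@`` and 1 to ``@``, and cis/trans configurations
are encoded with directional ``/`` and ``\\`` bonds, chaining correctly
through conjugated systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .graph import MolecularGraph, apply_permutation

__all__ = ["canonical_ranking", "canonical_key", "Traversal", "write_smiles"]

_ORGANIC = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
_BOND_SYMBOL = {1: "", 2: "=", 3: "#", 4: "$"}


def _renumber(keys: list) -> list[int]:
    order = {k: i for i, k in enumerate(sorted(set(keys)))}
    return [order[k] for k in keys]


def canonical_ranking(graph: MolecularGraph) -> tuple[int, ...]:
    """Canonical label (0-based, 0 = string start) for every atom."""
    n = graph.n_atoms
    adj = graph.adjacency
    neigh = [
        [(adj[i][j], j) for j in range(n) if adj[i][j]] for i in range(n)
    ]

    base = [
        (
            atom.element,
            atom.n_h,
            atom.valence,
            len(neigh[i]),
            tuple(sorted(order for order, _ in neigh[i])),
        )
        for i, atom in enumerate(graph.atoms)
    ]

    def refine(ranks: list[int]) -> list[int]:
        while True:
            keys = [
                (ranks[i], tuple(sorted((order, ranks[j]) for order, j in neigh[i])))
                for i in range(n)
            ]
            new = _renumber(keys)
            if new == ranks:
                return ranks
            ranks = new

    best: list | None = None

    def search(ranks: list[int]) -> None:
        nonlocal best
        ranks = refine(ranks)
        if len(set(ranks)) == n:
            key = _matrix_key(adj, ranks)
            if best is None or key < best[0]:
                best = [key, ranks]
            return
        counts: dict[int, int] = {}
        for r in ranks:
            counts[r] = counts.get(r, 0) + 1
        r0 = min(r for r, c in counts.items() if c > 1)
        for i in range(n):
            if ranks[i] == r0:
                branched = [2 * r for r in ranks]
                branched[i] -= 1
                search(branched)

    search(_renumber(base))
    assert best is not None
    return tuple(best[1])


def _matrix_key(adj, labels: Sequence[int]) -> tuple:
    perm = apply_permutation(adj, labels)
    n = len(labels)
    return tuple(perm[i][j] for i in range(n) for j in range(i + 1, n))


def canonical_key(graph: MolecularGraph) -> tuple:
    """Hashable invariant identifying the graph up to type-preserving
    relabeling; used e.g. to merge Kekulé duplicates."""
    labels = canonical_ranking(graph)
    inv = [None] * graph.n_atoms
    for i, l in enumerate(labels):
        inv[l] = graph.atoms[i]
    return (tuple(inv), _matrix_key(graph.adjacency, labels))


@dataclass
class Traversal:
    """Depth-first writing order of a graph under a canonical ranking.

    Fixes, for every atom, the order in which its neighbors appear in the
    output string; stereo parity bookkeeping relies on exactly this order.
    """

    graph: MolecularGraph
    labels: tuple[int, ...]
    order: list[int] = field(default_factory=list)  # atoms in visit order
    pos: dict[int, int] = field(default_factory=dict)
    parent: dict[int, int | None] = field(default_factory=dict)
    children: dict[int, list[int]] = field(default_factory=dict)
    rings: dict[int, list[tuple[int, int]]] = field(default_factory=dict)  # atom -> [(digit, partner)]

    def __post_init__(self):
        graph, labels = self.graph, self.labels
        n = graph.n_atoms
        by_label = sorted(range(n), key=lambda i: labels[i])
        start = by_label[0]
        visited = [False] * n
        ring_digit = [0]
        seen_bonds: set[frozenset] = set()

        def visit(i: int, par: int | None) -> None:
            visited[i] = True
            self.pos[i] = len(self.order)
            self.order.append(i)
            self.parent[i] = par
            self.children[i] = []
            self.rings.setdefault(i, [])
            for j in sorted(graph.neighbors(i), key=lambda j: labels[j]):
                bond = frozenset((i, j))
                if bond in seen_bonds:
                    continue
                seen_bonds.add(bond)
                if visited[j]:  # back edge: ring closure
                    ring_digit[0] += 1
                    d = ring_digit[0]
                    self.rings.setdefault(j, []).append((d, i))
                    self.rings[i].append((d, j))
                else:
                    self.children[i].append(j)
                    visit(j, i)

        visit(start, None)

    def neighbor_slots(self, i: int) -> list[object]:
        """Neighbors of *i* in string-appearance order.

        The slot sequence is: preceding atom, implicit hydrogens, ring
        closures in digit order, then branch atoms.  An implicit hydrogen
        is represented by the string ``"H"``; when the atom opens the
        string the hydrogen takes the (empty) preceding-atom slot.
        """
        slots: list[object] = []
        if self.parent[i] is not None:
            slots.append(self.parent[i])
        slots.extend(["H"] * self.graph.atoms[i].n_h)
        slots.extend(partner for _, partner in self.rings.get(i, []))
        slots.extend(self.children[i])
        return slots

    def single_bond_neighbors(self, i: int) -> list[int]:
        """Real singly-bonded neighbors of *i* ordered by string position."""
        adj = self.graph.adjacency
        return sorted(
            (j for j in self.graph.neighbors(i) if adj[i][j] == 1),
            key=lambda j: self.pos[j],
        )


def write_smiles(
    graph: MolecularGraph,
    labels: tuple[int, ...] | None = None,
    traversal: Traversal | None = None,
    tet_config: dict[int, int] | None = None,
    ct_config: list[tuple[tuple[int, int], tuple[int, int], int]] | None = None,
) -> str:
    """Write the canonical SMILES string, optionally stereo-annotated.

    ``tet_config`` maps tetrahedral stereocenter atoms to 0 (``@@``) or 1
    (``@``).  ``ct_config`` lists cis/trans centers as
    ``((h1, h2), (n1, n2), value)`` with the half-centers ordered by string
    position, their directionality neighbors, and 0 = trans / 1 = cis.
    """
    if traversal is None:
        if labels is None:
            labels = canonical_ranking(graph)
        traversal = Traversal(graph, labels)
    tet_config = tet_config or {}
    slashes = _assign_slashes(traversal, ct_config or [])
    adj = graph.adjacency

    def bond_text(a: int, b: int) -> str:
        order = adj[a][b]
        if order == 1:
            return slashes.get((a, b), "")
        return _BOND_SYMBOL[order]

    def atom_text(i: int) -> str:
        atom = graph.atoms[i]
        if i in tet_config:
            tag = "@" if tet_config[i] == 1 else "@@"
            h = "H" if atom.n_h == 1 else ""
            return f"[{atom.element}{tag}{h}]"
        if atom.element in _ORGANIC:
            return atom.element
        h = "" if atom.n_h == 0 else ("H" if atom.n_h == 1 else f"H{atom.n_h}")
        return f"[{atom.element}{h}]"

    def ring_text(i: int) -> str:
        parts = []
        for digit, partner in traversal.rings.get(i, []):
            sym = _BOND_SYMBOL[adj[i][partner]] if adj[i][partner] > 1 else ""
            parts.append(sym + (str(digit) if digit < 10 else f"%{digit:02d}"))
        return "".join(parts)

    def emit(i: int) -> str:
        out = atom_text(i) + ring_text(i)
        kids = traversal.children[i]
        for child in kids[:-1]:
            out += "(" + bond_text(i, child) + emit(child) + ")"
        if kids:
            out += bond_text(i, kids[-1]) + emit(kids[-1])
        return out

    return emit(traversal.order[0])


def _assign_slashes(
    traversal: Traversal,
    ct_config: list[tuple[tuple[int, int], tuple[int, int], int]],
) -> dict[tuple[int, int], str]:
    """Choose ``/`` and ``\\`` tokens for the directional single bonds.

    Stereo double bonds are processed in string order; a bond shared with an
    already-annotated conjugated neighbor keeps its token and the partner
    bond is chosen to realize the requested cis/trans relation.
    """
    parent = traversal.parent
    # chain value of a directional bond read a -> b: 0 for "/", 1 for "\\",
    # flipped when the bond is written in the opposite direction
    values: dict[frozenset, tuple[tuple[int, int], int]] = {}

    def chain_value(a: int, b: int) -> int | None:
        entry = values.get(frozenset((a, b)))
        if entry is None:
            return None
        (wa, _), v = entry
        return v if wa == a else v ^ 1

    def set_chain_value(a: int, b: int, v: int) -> None:
        # store relative to the written direction parent -> child
        if parent[b] == a:
            written = (a, b)
            wv = v
        else:
            written = (b, a)
            wv = v ^ 1
        values[frozenset((a, b))] = (written, wv)

    for (h1, h2), (n1, n2), bit in sorted(
        ct_config, key=lambda entry: traversal.pos[entry[0][0]]
    ):
        v1 = chain_value(n1, h1)
        if v1 is None:
            v1 = 0
            set_chain_value(n1, h1, v1)
        set_chain_value(h2, n2, v1 ^ bit)

    out: dict[tuple[int, int], str] = {}
    for (written, wv) in values.values():
        out[written] = "/" if wv == 0 else "\\"
    return out
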