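"""Orderly generation of canonical adjacency matrices.

Constitutional isomers are enumerated as lexicographically *maximal*
adjacency matrices over all type-preserving relabelings.  The generator
fills the upper triangle cell by cell in row-major order, trying larger
bond orders first, so complete matrices appear in strictly decreasing
lexicographic order.  Three pruning devices keep the search tree small:

* valence bookkeeping (a cell can never exceed the remaining valence of
  either atom, and the last cell of a row must consume the row's residue);
* realizability of the residual degree sequence on the unfilled atoms;
* a semi-canonicity test after every completed row: if some relabeling that
  maps the filled atom range onto itself makes the filled rows
  lexicographically larger, no completion of the branch can be canonical.

The canonicity test doubles as the automorphism-group computation: the
relabelings that reproduce the matrix exactly are exactly Aut(A).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

from .formula import ConcreteFormula
from .graph import VALENCES, MolecularGraph, UnitedAtom, atom_sort_key

__all__ = [
    "CanonicalIsomer",
    "distribute_hydrogens",
    "enumerate_canonical_matrices",
    "canonicalize",
]


@dataclass(frozen=True)
class CanonicalIsomer:
    """A canonical connected adjacency matrix with its automorphism group."""

    graph: MolecularGraph
    automorphisms: tuple[tuple[int, ...], ...]


def distribute_hydrogens(concrete: ConcreteFormula) -> list[tuple[UnitedAtom, ...]]:
    """All ways of absorbing the hydrogens into the heavy atoms.

    Returns the distinct united-atom multisets, each sorted in the canonical
    atom-type order.  Distributions that cannot possibly form a connected
    molecule (a zero effective valence in a multi-atom molecule, an odd
    valence sum, too little total valence to span a tree) are dropped.
    Pinned-H groups from the formula (``{CH1}`` etc.) are kept fixed.
    """
    counts = dict(concrete.counts)
    n_h = counts.pop("H", 0)
    pinned_atoms: list[UnitedAtom] = []
    free_counts: dict[str, int] = dict(counts)
    for element, h, c in concrete.pinned:
        pinned_atoms.extend([UnitedAtom.of(element, h)] * c)
        free_counts[element] -= c
        n_h -= h * c
        if free_counts[element] < 0:
            return []
    if n_h < 0:
        return []

    n_heavy = sum(counts.values())
    if n_heavy == 0:
        # pure hydrogen: only H2 is a molecule
        if n_h == 2:
            return [(UnitedAtom.of("H"), UnitedAtom.of("H"))]
        return []

    free_elements = [(e, c) for e, c in sorted(free_counts.items()) if c > 0]
    single_atom = n_heavy == 1

    per_element: list[list[tuple[int, tuple[int, ...]]]] = []
    for element, c in free_elements:
        delta = VALENCES[element]
        max_h = delta if single_atom else delta - 1
        options = [
            (sum(combo), combo)
            for combo in itertools.combinations_with_replacement(range(max_h + 1), c)
        ]
        per_element.append(options)

    partitions: list[tuple[UnitedAtom, ...]] = []
    seen: set[tuple[UnitedAtom, ...]] = set()
    for combo in itertools.product(*per_element):
        if sum(total for total, _ in combo) != n_h:
            continue
        atoms = list(pinned_atoms)
        for (element, _), (_, hs) in zip(free_elements, combo):
            atoms.extend(UnitedAtom.of(element, h) for h in hs)
        atoms.sort(key=atom_sort_key)
        key = tuple(atoms)
        if key in seen:
            continue
        seen.add(key)
        if _partition_feasible(atoms):
            partitions.append(key)
    return partitions


def _partition_feasible(atoms: Sequence[UnitedAtom]) -> bool:
    n = len(atoms)
    valences = [a.valence for a in atoms]
    if n == 1:
        return valences[0] == 0
    if any(v < 1 for v in valences):
        return False
    total = sum(valences)
    if total % 2 or total < 2 * (n - 1):
        return False
    return max(valences) <= total - max(valences)


def enumerate_canonical_matrices(
    atoms: Sequence[UnitedAtom], max_bond_order: int = 3
) -> Iterator[CanonicalIsomer]:
    """Emit every connected canonical matrix for the united-atom multiset.

    Matrices arrive in strictly decreasing lexicographic order, each paired
    with its complete automorphism group (identity included).
    """
    atoms = tuple(sorted(atoms, key=atom_sort_key))
    yield from _Enumerator(atoms, max_bond_order).run()


class _Enumerator:
    def __init__(self, atoms: tuple[UnitedAtom, ...], max_bond_order: int):
        self.atoms = atoms
        self.n = len(atoms)
        self.max_order = max_bond_order
        self.val = [a.valence for a in atoms]
        self.A = [[0] * self.n for _ in range(self.n)]
        self.rem = list(self.val)
        blocks: list[list[int]] = []
        for i, atom in enumerate(atoms):
            if blocks and atoms[blocks[-1][-1]] == atom:
                blocks[-1].append(i)
            else:
                blocks.append([i])
        self.blocks = blocks

    def run(self) -> Iterator[CanonicalIsomer]:
        if self.n == 0:
            return
        if self.n == 1:
            graph = MolecularGraph(self.atoms, ((0,),))
            yield CanonicalIsomer(graph, ((0,),))
            return
        yield from self._fill(0, 1)

    # -- matrix filling ----------------------------------------------------

    def _fill(self, r: int, c: int) -> Iterator[CanonicalIsomer]:
        n, A, rem = self.n, self.A, self.rem
        if c == n:
            yield from self._row_done(r)
            return
        # remaining capacity of this row must be able to absorb rem[r]
        cap = 0
        for j in range(c, n):
            cap += min(self.max_order, rem[j])
            if cap >= rem[r]:
                break
        if cap < rem[r]:
            return
        hi = min(rem[r], rem[c], self.max_order)
        lo = rem[r] if c == n - 1 else 0
        if lo > hi:
            return
        for v in range(hi, lo - 1, -1):
            A[r][c] = A[c][r] = v
            rem[r] -= v
            rem[c] -= v
            yield from self._fill(r, c + 1)
            rem[r] += v
            rem[c] += v
        A[r][c] = A[c][r] = 0

    def _row_done(self, r: int) -> Iterator[CanonicalIsomer]:
        n, A, rem = self.n, self.A, self.rem
        if rem[r] != 0:
            return
        if r + 1 < n:
            # a completed prefix with no bond into the suffix is a dead
            # (disconnected) branch
            crossing = any(A[k][j] for k in range(r + 1) for j in range(r + 1, n))
            if not crossing:
                return
            rest = rem[r + 1 :]
            total = sum(rest)
            if total % 2:
                return
            mx = max(rest)
            if mx > total - mx:
                return
        ok, auts = self._canonical_prefix(r)
        if not ok:
            return
        if r == n - 2:
            # all upper-triangle cells are filled; rem is all zero here
            matrix = tuple(tuple(row) for row in A)
            if _connected(matrix):
                graph = MolecularGraph(self.atoms, matrix)
                yield CanonicalIsomer(graph, tuple(auts))
            return
        yield from self._fill(r + 1, r + 2)

    # -- canonicity --------------------------------------------------------

    def _canonical_prefix(self, r: int) -> tuple[bool, list[tuple[int, ...]]]:
        """Test rows 0..r for lexicographic maximality.

        For a partial matrix only relabelings mapping {0..r} onto itself are
        considered (sound: such a relabeling of any completion would already
        be larger in the filled rows).  For the complete matrix (r == n-2)
        every type-preserving relabeling is considered and those achieving
        equality are returned as the automorphism group.
        """
        n, A = self.n, self.A
        full = r >= n - 2
        limit = n - 1 if full else r
        auts: list[tuple[int, ...]] = []
        q = [0] * n

        def rec(row: int, cells: list[tuple[list[int], list[int]]]) -> bool:
            # returns True when a lexicographically larger relabeling exists
            if row > limit:
                if full:
                    pi = [0] * n
                    for t in range(n):
                        pi[q[t]] = t
                    auts.append(tuple(pi))
                return False
            ci = next(i for i, (ps, _) in enumerate(cells) if ps[0] == row)
            positions, sources = cells[ci]
            rest_positions = positions[1:]
            rowA = A[row]
            for s in sources:
                if not full and s > limit:
                    continue
                q[row] = s
                rowS = A[s]
                # greedy lexicographic maximum of the permuted row
                iter_cells = []
                if rest_positions:
                    iter_cells.append(
                        (rest_positions, [x for x in sources if x != s])
                    )
                for i, cell in enumerate(cells):
                    if i != ci:
                        iter_cells.append(cell)
                iter_cells.sort(key=lambda cell: cell[0][0])
                verdict = 0  # -1 smaller, 0 equal, +1 larger
                first_diff = n + 1
                for k, (ps, ss) in enumerate(iter_cells):
                    if verdict and first_diff < ps[0]:
                        break  # later cells cannot precede the difference
                    if len(ps) == 1:
                        v = rowS[ss[0]]
                        pos = ps[0]
                        if v != rowA[pos] and pos < first_diff:
                            first_diff = pos
                            verdict = 1 if v > rowA[pos] else -1
                        continue
                    vals = sorted((rowS[x] for x in ss), reverse=True)
                    for pos, v in zip(ps, vals):
                        if v != rowA[pos] and pos < first_diff:
                            first_diff = pos
                            verdict = 1 if v > rowA[pos] else -1
                if verdict == 1:
                    return True
                if verdict == -1:
                    continue
                # equal: refine every cell by the realized value
                refined: list[tuple[list[int], list[int]]] = []
                for ps, ss in iter_cells:
                    if len(ps) == 1:
                        refined.append((ps, ss))
                        continue
                    groups: dict[int, tuple[list[int], list[int]]] = {}
                    for pos in ps:
                        g = groups.get(rowA[pos])
                        if g is None:
                            groups[rowA[pos]] = g = ([], [])
                        g[0].append(pos)
                    for x in ss:
                        groups[rowS[x]][1].append(x)
                    refined.extend(groups.values())
                refined.sort(key=lambda cell: cell[0][0])
                if rec(row + 1, refined):
                    return True
            return False

        cells0 = [(list(b), list(b)) for b in self.blocks]
        larger = rec(0, cells0)
        return (not larger, auts)


def canonicalize(graph: MolecularGraph) -> CanonicalIsomer:
    """Canonical form and automorphism group of an arbitrarily labeled graph.

    Exhaustive maximization over all type-preserving relabelings -- intended
    for fixtures and small molecules, not for enumeration-scale work.
    """
    order = sorted(range(graph.n_atoms), key=lambda i: atom_sort_key(graph.atoms[i]))
    perm = [0] * graph.n_atoms
    for new, old in enumerate(order):
        perm[old] = new
    sorted_graph = graph.relabeled(perm)
    atoms = sorted_graph.atoms
    blocks: list[list[int]] = []
    for i, atom in enumerate(atoms):
        if blocks and atoms[blocks[-1][-1]] == atom:
            blocks[-1].append(i)
        else:
            blocks.append([i])
    from .graph import apply_permutation, lex_compare

    best = None
    best_perms: list[tuple[int, ...]] = []
    for pieces in itertools.product(*(itertools.permutations(b) for b in blocks)):
        pi = [0] * len(atoms)
        for block, piece in zip(blocks, pieces):
            for src, dst in zip(block, piece):
                pi[src] = dst
        candidate = apply_permutation(sorted_graph.adjacency, pi)
        if best is None or lex_compare(candidate, best) > 0:
            best = candidate
            best_perms = [tuple(pi)]
        elif lex_compare(candidate, best) == 0:
            best_perms.append(tuple(pi))
    canonical = MolecularGraph(atoms, best)
    # automorphisms of the canonical matrix: pairwise differences of the
    # permutations that all reach the same maximal matrix
    base = best_perms[0]
    inv_base = [0] * len(base)
    for i, v in enumerate(base):
        inv_base[v] = i
    auts = []
    for p in best_perms:
        pi = tuple(p[inv_base[t]] for t in range(len(base)))
        auts.append(pi)
    return CanonicalIsomer(canonical, tuple(auts))


def _connected(matrix: Sequence[Sequence[int]]) -> bool:
    n = len(matrix)
    seen = [False] * n
    seen[0] = True
    stack = [0]
    count = 1
    while stack:
        i = stack.pop()
        row = matrix[i]
        for j in range(n):
            if row[j] and not seen[j]:
                seen[j] = True
                count += 1
                stack.append(j)
    return count == n
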