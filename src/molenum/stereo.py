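"""Stereocenter detection and stereoisomer enumeration.

Two kinds of stereo elements are handled: tetrahedral centers (an atom with
four singly-bonded substituents, implicit hydrogen included) and cis/trans
double bonds (two tetravalent half-centers joined by a double bond, each
with two singly-bonded substituents, neither atom in a cycle).

A center is *true* when its substituents differ constitutionally -- either
visibly (all four first neighbors of different united type) or because no
automorphism of the adjacency matrix fixes the center while swapping two of
its first neighbors.  A center whose substituents are constitutionally
identical but may differ in stereo configuration is a *para* center; it is
active or inactive depending on the configurations of the other centers.

Stereoisomers are encoded as configuration vectors over the centers in
string order (0/1 for true centers, -1/0/1 for para centers with -1 =
inactive) and deduplicated under the automorphism group with the local
parity rules of the SMILES notation: an even permutation of a center's
neighbor order preserves the encoding, an odd one flips it.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

from .enumerate import CanonicalIsomer
from .graph import MolecularGraph
from .smiles import Traversal, canonical_ranking, write_smiles

__all__ = ["StereoModel", "StereoIsomer", "build_stereo_model", "enumerate_stereoisomers"]


@dataclass(frozen=True)
class Center:
    kind: str  # "tet" | "ct"
    atoms: tuple[int, ...]  # (a,) or (h1, h2) ordered by string position


@dataclass
class StereoModel:
    """Detected stereocenters of one constitutional isomer."""

    graph: MolecularGraph
    traversal: Traversal
    automorphisms: tuple[tuple[int, ...], ...]
    true_centers: list[Center]
    para_centers: list[Center]
    slots: dict[int, tuple]  # tetrahedral neighbor order in the string
    dir_neighbors: dict[tuple[int, int], tuple[int, int]]  # ct pair -> (n1, n2)

    @property
    def n_tet(self) -> int:
        return sum(1 for c in self.true_centers if c.kind == "tet")

    @property
    def n_ct(self) -> int:
        return sum(1 for c in self.true_centers if c.kind == "ct")


@dataclass
class StereoIsomer:
    """One unique stereoisomer: configurations of the true and para centers."""

    true_config: tuple[int, ...]
    para_config: tuple[int, ...]
    smiles: str
    n_tet: int
    n_ct: int
    enantiomer: int | None = None  # index into the sibling list


# ---------------------------------------------------------------------------
# detection


def _cycle_atoms(graph: MolecularGraph) -> set[int]:
    """Atoms lying on at least one cycle (incident to a non-bridge edge)."""
    bonds = [(i, j) for i, j, _ in graph.bonds()]
    n = graph.n_atoms
    out: set[int] = set()
    for i, j in bonds:
        # edge lies on a cycle iff its removal keeps the graph connected
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in graph.neighbors(u):
                if {u, v} == {i, j}:
                    continue
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) == n:
            out.update((i, j))
    return out


def _distances_from(graph: MolecularGraph, start: int) -> list[int]:
    n = graph.n_atoms
    dist = [-1] * n
    dist[start] = 0
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in graph.neighbors(u):
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def build_stereo_model(isomer: CanonicalIsomer, traversal: Traversal | None = None) -> StereoModel:
    graph = isomer.graph
    if traversal is None:
        traversal = Traversal(graph, canonical_ranking(graph))
    aut = isomer.automorphisms
    adj = graph.adjacency
    atoms = graph.atoms
    cycle_atoms = _cycle_atoms(graph)

    def unit_type(j: int):
        return (atoms[j].element, atoms[j].n_h)

    # -- tetrahedral candidates -------------------------------------------
    true_tet: list[int] = []
    para_tet: list[int] = []
    for i in range(graph.n_atoms):
        nbrs = graph.neighbors(i)
        if atoms[i].full_valence != 4 or atoms[i].valence != len(nbrs):
            continue  # needs four substituents, all singly bonded
        if atoms[i].n_h >= 2:
            continue  # two identical hydrogens
        items = [unit_type(j) for j in nbrs] + ["H"] * atoms[i].n_h
        if len(set(items)) == 4:
            true_tet.append(i)
            continue
        # two identical monovalent substituents can never be distinguished
        types = [unit_type(j) for j in nbrs]
        if any(
            types.count(t) >= 2 and atoms[nbrs[types.index(t)]].valence == 1
            for t in set(types)
        ):
            continue
        if any(pi[i] == i and any(pi[j] != j for j in nbrs) for pi in aut):
            para_tet.append(i)
        else:
            true_tet.append(i)

    # -- cis/trans half-centers -------------------------------------------
    # classification: 2 = potential true half, 1 = para half, 0 = no
    half: dict[int, int] = {}
    for i in range(graph.n_atoms):
        if atoms[i].full_valence != 4 or i in cycle_atoms:
            continue
        orders = [adj[i][j] for j in graph.neighbors(i)]
        if orders.count(2) != 1 or any(o > 2 for o in orders):
            continue
        singles = [j for j in graph.neighbors(i) if adj[i][j] == 1]
        if len(singles) + atoms[i].n_h != 2:
            continue
        if atoms[i].n_h == 2:
            continue  # two identical hydrogens
        if len(singles) == 2 and unit_type(singles[0]) == unit_type(singles[1]):
            if atoms[singles[0]].valence == 1:
                continue  # identical monovalent substituents
            if any(pi[i] == i and pi[singles[0]] == singles[1] for pi in aut):
                half[i] = 1
                continue
        half[i] = 2

    pos = traversal.pos
    true_ct: list[tuple[int, int]] = []
    para_ct: list[tuple[int, int]] = []
    for i, j, order in graph.bonds():
        if order != 2 or i not in half or j not in half:
            continue
        pair = (i, j) if pos[i] < pos[j] else (j, i)
        if half[i] == 2 and half[j] == 2:
            true_ct.append(pair)
        else:
            # a half rejected only by the automorphism test, or a sound half
            # whose partner was, still forms a para candidate pair
            para_ct.append(pair)

    true_centers = sorted(
        [Center("tet", (a,)) for a in true_tet]
        + [Center("ct", p) for p in true_ct],
        key=lambda c: pos[c.atoms[0]],
    )

    para_centers = _retain_para(
        graph, aut, cycle_atoms,
        [Center("tet", (a,)) for a in para_tet] + [Center("ct", p) for p in para_ct],
        true_centers,
    )
    para_centers.sort(key=lambda c: pos[c.atoms[0]])

    slots = {
        c.atoms[0]: tuple(traversal.neighbor_slots(c.atoms[0]))
        for c in true_centers + para_centers
        if c.kind == "tet"
    }
    dirn: dict[tuple[int, int], tuple[int, int]] = {}
    for c in true_centers + para_centers:
        if c.kind == "ct":
            h1, h2 = c.atoms
            dirn[c.atoms] = (
                traversal.single_bond_neighbors(h1)[0],
                traversal.single_bond_neighbors(h2)[0],
            )

    return StereoModel(graph, traversal, aut, true_centers, para_centers, slots, dirn)


def _retain_para(
    graph: MolecularGraph,
    aut: Sequence[Sequence[int]],
    cycle_atoms: set[int],
    candidates: list[Center],
    true_centers: list[Center],
) -> list[Center]:
    """Keep a para candidate if it lies in a cycle or in the middle of the
    shortest path between a pair of automorphism-swapped true centers.

    A para center can only become active through configurationally distinct
    substituents, which ultimately requires true stereocenters somewhere in
    the molecule; ring para centers that would depend only on other para
    centers (the 1,4-dimethylcyclohexane situation) are deliberately not
    enumerated."""
    if not candidates or not true_centers:
        return []
    kept: list[Center] = []
    dists = {}

    def dist_rows(center: Center):
        if center.atoms not in dists:
            dists[center.atoms] = [_distances_from(graph, a) for a in center.atoms]
        return dists[center.atoms]

    sym_pairs: list[tuple[Center, Center]] = []
    for a, b in itertools.combinations(true_centers, 2):
        sa, sb = set(a.atoms), set(b.atoms)
        if any({pi[x] for x in sa} == sb for pi in aut):
            sym_pairs.append((a, b))

    for cand in candidates:
        if any(a in cycle_atoms for a in cand.atoms):
            kept.append(cand)
            continue
        retained = False
        for s, t in sym_pairs:
            ds = dist_rows(s)
            dt = dist_rows(t)
            d_st = min(r[a] for r in ds for a in t.atoms)
            for m in cand.atoms:
                dm_s = min(r[m] for r in ds)
                dm_t = min(r[m] for r in dt)
                if dm_s == dm_t and dm_s + dm_t == d_st:
                    retained = True
                    break
            if retained:
                break
        if retained:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# parity transport


def _perm_parity(seq: Sequence[int]) -> int:
    """0 for an even permutation of 0..n-1, 1 for an odd one."""
    seen = [False] * len(seq)
    parity = 0
    for i in range(len(seq)):
        if seen[i]:
            continue
        j = i
        length = 0
        while not seen[j]:
            seen[j] = True
            j = seq[j]
            length += 1
        parity ^= (length - 1) & 1
    return parity


def _transport(model: StereoModel, pi: Sequence[int], src: Center, dst: Center, value: int) -> int:
    """Configuration of *dst* induced by *src*'s value under automorphism *pi*."""
    if value == -1:
        return -1
    if src.kind == "tet":
        n_src = model.slots[src.atoms[0]]
        n_dst = model.slots[dst.atoms[0]]
        mapped = ["H" if x == "H" else pi[x] for x in n_src]
        perm = [n_dst.index(x) for x in mapped]
        return value ^ _perm_parity(perm)
    h1, h2 = src.atoms
    d1, d2 = dst.atoms
    n1, n2 = model.dir_neighbors[src.atoms]
    m1, m2 = model.dir_neighbors[dst.atoms]
    if pi[h1] == d1:
        img1, img2 = pi[n1], pi[n2]
    else:  # halves swapped across the pair
        img1, img2 = pi[n2], pi[n1]
    flip = (img1 != m1) ^ (img2 != m2)
    return value ^ (1 if flip else 0)


def permute_vector(
    model: StereoModel,
    pi: Sequence[int],
    centers: Sequence[Center],
    vector: Sequence[int],
) -> tuple[int, ...]:
    """Configuration vector after relabeling the molecule by *pi*."""
    index = {c.atoms[0]: k for k, c in enumerate(centers)}
    for c in centers:
        if c.kind == "ct":
            index[c.atoms[1]] = index[c.atoms[0]]
    out = [0] * len(centers)
    for k, src in enumerate(centers):
        dst_k = index[pi[src.atoms[0]]]
        out[dst_k] = _transport(model, pi, src, centers[dst_k], vector[k])
    return tuple(out)


def _collapse(vector: Iterable[int]) -> tuple[int, ...]:
    return tuple(0 if v == -1 else v for v in vector)


# ---------------------------------------------------------------------------
# enumeration


def enumerate_true_vectors(model: StereoModel) -> list[tuple[int, ...]]:
    """Unique configuration vectors of the true stereocenters."""
    centers = model.true_centers
    if not centers:
        return [()]
    aut = model.automorphisms
    out = []
    for bits in itertools.product((0, 1), repeat=len(centers)):
        if any(permute_vector(model, pi, centers, bits) < bits for pi in aut):
            continue
        out.append(bits)
    return out


def _fixes_and_swaps(model: StereoModel, pi: Sequence[int], center: Center) -> bool:
    """Does *pi* leave the center in place while swapping two of its
    immediate neighbors?"""
    if center.kind == "tet":
        a = center.atoms[0]
        return pi[a] == a and any(pi[j] != j for j in model.graph.neighbors(a))
    h1, h2 = center.atoms
    if pi[h1] != h1 or pi[h2] != h2:
        return False
    adj = model.graph.adjacency
    for h in (h1, h2):
        singles = [j for j in model.graph.neighbors(h) if adj[h][j] == 1]
        if len(singles) == 2 and pi[singles[0]] == singles[1]:
            return True
    return False


def enumerate_para_vectors(
    model: StereoModel, true_vector: tuple[int, ...]
) -> list[tuple[int, ...]]:
    """Unique para configuration vectors for one true stereoisomer.

    Aut^true is the subgroup preserving the true configuration; within each
    binary para vector, centers fixed by an Aut^para element that swaps two
    of their neighbors are deactivated (entry -1) iteratively to a fixed
    point.  Vectors are deduplicated under Aut^true with -1 read as 0.
    """
    centers = model.para_centers
    aut_true = [
        pi
        for pi in model.automorphisms
        if permute_vector(model, pi, model.true_centers, true_vector) == tuple(true_vector)
    ]
    if not centers:
        return [()]
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    for bits in itertools.product((0, 1), repeat=len(centers)):
        p = list(bits)
        while True:
            aut_para = [
                pi
                for pi in aut_true
                if permute_vector(model, pi, centers, p) == tuple(p)
            ]
            changed = False
            for k, center in enumerate(centers):
                if p[k] == -1:
                    continue
                if any(_fixes_and_swaps(model, pi, center) for pi in aut_para):
                    p[k] = -1
                    changed = True
            if not changed:
                break
        key = min(
            _collapse(permute_vector(model, pi, centers, p)) for pi in aut_true
        )
        if key in seen:
            continue
        seen.add(key)
        out.append(tuple(p))
    return out


def _stereo_smiles(model: StereoModel, tvec: Sequence[int], pvec: Sequence[int]) -> str:
    tet_config: dict[int, int] = {}
    ct_config: list[tuple[tuple[int, int], tuple[int, int], int]] = []
    for centers, vec in ((model.true_centers, tvec), (model.para_centers, pvec)):
        for c, v in zip(centers, vec):
            if v == -1:
                continue
            if c.kind == "tet":
                tet_config[c.atoms[0]] = v
            else:
                ct_config.append((c.atoms, model.dir_neighbors[c.atoms], v))
    return write_smiles(
        model.graph,
        traversal=model.traversal,
        tet_config=tet_config,
        ct_config=ct_config,
    )


def enumerate_stereoisomers(model: StereoModel) -> list[StereoIsomer]:
    """All unique stereoisomers of one constitutional isomer.

    A molecule without stereocenters yields exactly one entry.  Enantiomer
    cross-references are filled in for molecules with at least one
    tetrahedral center; a stereoisomer that is its own mirror image (meso)
    gets none.
    """
    isomers: list[StereoIsomer] = []
    for tvec in enumerate_true_vectors(model):
        for pvec in enumerate_para_vectors(model, tvec):
            n_tet = sum(
                1
                for c, v in zip(model.true_centers, tvec)
                if c.kind == "tet"
            ) + sum(
                1
                for c, v in zip(model.para_centers, pvec)
                if c.kind == "tet" and v != -1
            )
            n_ct = sum(
                1 for c in model.true_centers if c.kind == "ct"
            ) + sum(
                1
                for c, v in zip(model.para_centers, pvec)
                if c.kind == "ct" and v != -1
            )
            isomers.append(
                StereoIsomer(tvec, tuple(pvec), _stereo_smiles(model, tvec, pvec), n_tet, n_ct)
            )
    _link_enantiomers(model, isomers)
    return isomers


def _mirror(model: StereoModel, iso: StereoIsomer) -> tuple[tuple[int, ...], tuple[int, ...]]:
    t = tuple(
        v ^ 1 if c.kind == "tet" else v
        for c, v in zip(model.true_centers, iso.true_config)
    )
    p = tuple(
        v ^ 1 if c.kind == "tet" and v != -1 else v
        for c, v in zip(model.para_centers, iso.para_config)
    )
    return t, p


def _equivalent(model: StereoModel, a: tuple, b: tuple) -> bool:
    ta, pa = a
    tb, pb = b
    for pi in model.automorphisms:
        if permute_vector(model, pi, model.true_centers, ta) == tb and _collapse(
            permute_vector(model, pi, model.para_centers, pa)
        ) == _collapse(pb):
            return True
    return False


def _link_enantiomers(model: StereoModel, isomers: list[StereoIsomer]) -> None:
    has_tet = any(c.kind == "tet" for c in model.true_centers + model.para_centers)
    if not has_tet:
        return
    for idx, iso in enumerate(isomers):
        mirror = _mirror(model, iso)
        for jdx, other in enumerate(isomers):
            if _equivalent(model, mirror, (other.true_config, other.para_config)):
                iso.enantiomer = None if jdx == idx else jdx
                break
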