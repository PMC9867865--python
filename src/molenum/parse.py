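"""Minimal SMILES reader for fixtures and substructure patterns.

Supports plain element symbols, brackets with an explicit H count, bond
symbols ``- = # $``, branches and ring-closure digits.  Stereo markers and
aromatic lowercase forms are not read; hydrogens left implicit are filled
in from the fixed element valences.  Third-party parsers remain the
round-trip oracle in the tests -- this reader only builds internal graphs
from hand-written structures.
"""

from __future__ import annotations

import re

from .graph import VALENCES, MolecularGraph, UnitedAtom

__all__ = ["parse_smiles", "parse_pattern"]

_BOND = {"-": 1, "=": 2, "#": 3, "$": 4}
_ATOM = re.compile(
    r"\[(?P<bel>[A-Z][a-z]?|\*)(?:H(?P<bh>\d*))?\]|(?P<el>Cl|Br|[BCNOPSFI]|\*)"
)


def _parse_core(text: str):
    """Tokenize a SMILES string into elements, explicit-H counts and bonds."""
    elements: list[str] = []
    explicit_h: list[int | None] = []
    bonds: dict[frozenset, int] = {}
    stack: list[int] = []
    rings: dict[str, tuple[int, int]] = {}
    prev: int | None = None
    order = 1
    i = 0
    while i < len(text):
        ch = text[i]
        if ch in _BOND:
            order = _BOND[ch]
            i += 1
            continue
        if ch in "/\\":
            i += 1  # directional marks are ignored by the constitutional reader
            continue
        if ch == "(":
            stack.append(prev)
            i += 1
            continue
        if ch == ")":
            prev = stack.pop()
            i += 1
            continue
        if ch.isdigit() or ch == "%":
            if ch == "%":
                digit, i = text[i + 1 : i + 3], i + 3
            else:
                digit, i = ch, i + 1
            if digit in rings:
                j, ring_order = rings.pop(digit)
                bonds[frozenset((prev, j))] = max(ring_order, order)
            else:
                rings[digit] = (prev, order)
            order = 1
            continue
        m = _ATOM.match(text, i)
        if not m:
            raise ValueError(f"cannot read SMILES at {text[i:]!r}")
        if m.group("bel"):
            element = m.group("bel")
            h = int(m.group("bh") or 1) if m.group("bh") is not None else 0
        else:
            element = m.group("el")
            h = None
        if element != "*" and element not in VALENCES:
            raise ValueError(f"unsupported element {element!r}")
        idx = len(elements)
        elements.append(element)
        explicit_h.append(h)
        if prev is not None:
            bonds[frozenset((prev, idx))] = order
        prev = idx
        order = 1
        i = m.end()
    if rings:
        raise ValueError("unclosed ring bond")
    return elements, explicit_h, bonds


def parse_smiles(text: str) -> MolecularGraph:
    """Parse a constitutional SMILES string into a united-atom graph."""
    elements, explicit_h, bonds = _parse_core(text)
    if "*" in elements:
        raise ValueError("wildcard atoms are only allowed in patterns")
    n = len(elements)
    a = [[0] * n for _ in range(n)]
    for bond, bond_order in bonds.items():
        u, v = tuple(bond)
        a[u][v] = a[v][u] = bond_order
    atoms = []
    for k in range(n):
        used = sum(a[k])
        n_h = explicit_h[k]
        if n_h is None:
            n_h = VALENCES[elements[k]] - used
        if n_h < 0 or used + n_h > VALENCES[elements[k]]:
            raise ValueError(f"valence of atom {k} ({elements[k]}) exceeded")
        atoms.append(UnitedAtom.of(elements[k], n_h))
    return MolecularGraph(tuple(atoms), tuple(tuple(r) for r in a))


def parse_pattern(text: str):
    """Parse a SMILES string as a substructure pattern.

    Returns ``(atoms, matrix)`` where every plain atom becomes a bare
    element symbol (matching any attached-H count), a bracket atom becomes
    an ``(element, n_h)`` pair, and ``*`` is the wildcard.
    """
    elements, explicit_h, bonds = _parse_core(text)
    n = len(elements)
    matrix = [[0] * n for _ in range(n)]
    for bond, bond_order in bonds.items():
        u, v = tuple(bond)
        matrix[u][v] = matrix[v][u] = bond_order
    atoms = [
        e if h is None else (e, h) for e, h in zip(elements, explicit_h)
    ]
    return atoms, matrix
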