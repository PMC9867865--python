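"""Molecular-formula mini-language.

A formula is a sequence of atom specifications, each carrying a count set::

    C6H14            single integers
    H[0,2,4,5]       a list of counts
    C[1-20]H[4-42]   an inclusive range
    {CH1}1{CH2}2{OH1}3   united atoms with a fixed attached-H count

``{CH1}2`` reads "two carbon atoms each bonded to exactly one hydrogen";
the hydrogens enter the total H count of the expanded formula but stay
pinned to their heavy atom during enumeration.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterator

from .graph import VALENCES, unsaturations

__all__ = ["ElementSpec", "MolecularFormula", "ConcreteFormula", "parse_formula", "FormulaError"]


class FormulaError(ValueError):
    """Malformed formula text; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class ElementSpec:
    """One atom type in a formula: element, fixed valence, optional pinned H."""

    symbol: str
    valence: int
    implicit_h: int | None = None

    def __post_init__(self):
        if self.valence < 1:
            raise ValueError("valence must be positive")
        if self.implicit_h is not None and not 0 <= self.implicit_h <= self.valence:
            raise ValueError("implicit hydrogen count exceeds the valence")


@dataclass(frozen=True)
class ConcreteFormula:
    """A fully expanded formula: exact element counts plus pinned-H groups.

    ``counts`` includes *all* hydrogens (pinned ones too); ``pinned`` lists
    ``(element, n_h, count)`` groups that must appear as united atoms with
    exactly ``n_h`` attached hydrogens.
    """

    counts: tuple[tuple[str, int], ...]
    pinned: tuple[tuple[str, int, int], ...] = ()

    def count(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    @property
    def n_heavy(self) -> int:
        return sum(n for e, n in self.counts if e != "H")

    def unsaturations(self) -> int:
        return unsaturations(dict(self.counts))

    def is_feasible(self) -> bool:
        """Even valence sum and a non-negative unsaturation count."""
        try:
            return self.unsaturations() >= 0
        except ValueError:
            return False

    def __str__(self) -> str:
        # Hill convention: carbon, hydrogen, then the rest alphabetically
        order = sorted(self.counts, key=lambda en: (en[0] != "C", en[0] != "H", en[0]))
        return "".join(f"{e}{n}" if n > 1 else e for e, n in order if n)


_TOKEN = re.compile(
    r"\{(?P<pel>[A-Z][a-z]?)H(?P<ph>\d+)\}(?P<pcount>\d+|\[[^\]]*\])?"
    r"|(?P<el>[A-Z][a-z]?)(?P<count>\d+|\[[^\]]*\])?"
)


def _parse_count_set(text: str | None, pos: int) -> tuple[int, ...]:
    if text is None:
        return (1,)
    if not text.startswith("["):
        return (int(text),)
    body = text[1:-1].strip()
    if not body:
        raise FormulaError("empty count set", pos)
    values: list[int] = []
    for part in body.split(","):
        part = part.strip()
        m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", part)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if hi < lo:
                raise FormulaError(f"empty range {part!r}", pos)
            values.extend(range(lo, hi + 1))
        elif re.fullmatch(r"\d+", part):
            values.append(int(part))
        else:
            raise FormulaError(f"malformed count {part!r}", pos)
    return tuple(sorted(set(values)))


@dataclass(frozen=True)
class MolecularFormula:
    """Parsed formula: ordered atom specs, each with a finite count set."""

    specs: tuple[tuple[ElementSpec, tuple[int, ...]], ...] = field(default=())

    def expand(self) -> Iterator[ConcreteFormula]:
        """All concrete formulas from the cross product of the count sets.

        Chemically impossible combinations (odd valence sum, negative
        unsaturations, no atoms) are skipped.
        """
        choices = [counts for _, counts in self.specs]
        for combo in itertools.product(*choices):
            counts: dict[str, int] = {}
            pinned: dict[tuple[str, int], int] = {}
            for (spec, _), n in zip(self.specs, combo):
                if n == 0:
                    continue
                counts[spec.symbol] = counts.get(spec.symbol, 0) + n
                if spec.implicit_h is not None:
                    counts["H"] = counts.get("H", 0) + n * spec.implicit_h
                    key = (spec.symbol, spec.implicit_h)
                    pinned[key] = pinned.get(key, 0) + n
            n_heavy = sum(n for e, n in counts.items() if e != "H")
            if n_heavy == 0 and counts.get("H", 0) != 2:
                continue  # with no heavy atoms only H2 is a molecule
            concrete = ConcreteFormula(
                tuple(sorted(counts.items())),
                tuple(sorted((e, h, c) for (e, h), c in pinned.items())),
            )
            if concrete.is_feasible():
                yield concrete


def parse_formula(text: str) -> MolecularFormula:
    """Parse the formula mini-language into a :class:`MolecularFormula`."""
    specs: list[tuple[ElementSpec, tuple[int, ...]]] = []
    pos = 0
    stripped = text.strip()
    while pos < len(stripped):
        m = _TOKEN.match(stripped, pos)
        if not m:
            raise FormulaError(f"unexpected token {stripped[pos:pos+8]!r}", pos)
        if m.group("pel"):
            element, n_h = m.group("pel"), int(m.group("ph"))
            count_text = m.group("pcount")
        else:
            element, n_h = m.group("el"), None
            count_text = m.group("count")
        if element not in VALENCES:
            raise FormulaError(f"unknown element {element!r}", pos)
        try:
            spec = ElementSpec(element, VALENCES[element], n_h)
        except ValueError as exc:
            raise FormulaError(str(exc), pos) from None
        specs.append((spec, _parse_count_set(count_text, pos)))
        pos = m.end()
    if not specs:
        raise FormulaError("empty formula", 0)
    return MolecularFormula(tuple(specs))


def render_formula(formula: MolecularFormula) -> str:
    """Inverse of :func:`parse_formula` on normalized input."""
    parts = []
    for spec, counts in formula.specs:
        head = f"{{{spec.symbol}H{spec.implicit_h}}}" if spec.implicit_h is not None else spec.symbol
        if len(counts) == 1:
            parts.append(f"{head}{counts[0]}" if counts[0] != 1 or spec.implicit_h is not None else head)
        elif counts == tuple(range(counts[0], counts[-1] + 1)):
            parts.append(f"{head}[{counts[0]}-{counts[-1]}]")
        else:
            parts.append(f"{head}[{','.join(map(str, counts))}]")
    return "".join(parts)
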