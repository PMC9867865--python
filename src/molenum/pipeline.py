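"""High-level enumeration pipeline: formula in, isomer records out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Sequence

from .enumerate import CanonicalIsomer, distribute_hydrogens, enumerate_canonical_matrices
from .filters import RestrictionSet, Substructure, aromatic_key, count_substructure, passes_filters
from .formula import ConcreteFormula, MolecularFormula, parse_formula
from .smiles import Traversal, canonical_ranking, write_smiles
from .stereo import StereoIsomer, build_stereo_model, enumerate_stereoisomers

__all__ = ["IsomerRecord", "enumerate_isomers", "count_isomers"]


@dataclass
class IsomerRecord:
    """One constitutional isomer with its stereo expansion."""

    formula: str
    smiles: str
    n_tet: int
    n_ct: int
    stereoisomers: list[StereoIsomer]
    isomer: CanonicalIsomer


def enumerate_isomers(
    formula: str | MolecularFormula,
    restrictions: RestrictionSet | None = None,
    substructures: Sequence[Substructure] = (),
    stereo: bool = True,
    progress: Callable[[str, int], None] | None = None,
    progress_every: int = 100,
) -> Iterator[IsomerRecord]:
    """Enumerate all constitutional isomers (and their stereoisomers).

    The unsaturation restriction is applied per concrete formula before any
    matrix is generated; bond/cycle/substructure restrictions are applied
    per emitted isomer, and only survivors are stereo-expanded.  Kekulé
    duplicates of six-ring aromatics are merged.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    restrictions = restrictions or RestrictionSet()
    counter = 0
    for concrete in formula.expand():
        if not restrictions.admits_unsaturations(concrete.unsaturations()):
            continue
        name = str(concrete)
        seen_aromatic: set = set()
        for isomer in _formula_isomers(concrete, restrictions.max_bond_order):
            graph = isomer.graph
            if not passes_filters(graph, restrictions):
                continue
            if not all(
                sub.occurrences is None
                or count_substructure(graph, sub) in sub.occurrences
                for sub in substructures
            ):
                continue
            key = aromatic_key(graph)
            if key is not None:
                if key in seen_aromatic:
                    continue
                seen_aromatic.add(key)
            labels = canonical_ranking(graph)
            traversal = Traversal(graph, labels)
            smiles = write_smiles(graph, traversal=traversal)
            if stereo:
                model = build_stereo_model(isomer, traversal)
                stereoisomers = enumerate_stereoisomers(model)
                n_tet, n_ct = model.n_tet, model.n_ct
            else:
                stereoisomers = []
                n_tet = n_ct = 0
            record = IsomerRecord(name, smiles, n_tet, n_ct, stereoisomers, isomer)
            counter += len(stereoisomers) or 1
            if progress is not None and counter // progress_every != (
                counter - (len(stereoisomers) or 1)
            ) // progress_every:
                progress(name, counter)
            yield record


def _formula_isomers(
    concrete: ConcreteFormula, max_bond_order: int
) -> Iterator[CanonicalIsomer]:
    for partition in distribute_hydrogens(concrete):
        yield from enumerate_canonical_matrices(partition, max_bond_order)


def count_isomers(
    formula: str | MolecularFormula,
    restrictions: RestrictionSet | None = None,
    substructures: Sequence[Substructure] = (),
    stereo: bool = True,
) -> tuple[int, int]:
    """(constitutional, spatial) counts; spatial is 0 when stereo is off."""
    n_const = n_spatial = 0
    for record in enumerate_isomers(
        formula, restrictions, substructures, stereo=stereo
    ):
        n_const += 1
        n_spatial += len(record.stereoisomers)
    return n_const, n_spatial
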