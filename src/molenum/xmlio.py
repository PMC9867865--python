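"""XML output for enumeration results.

Records are grouped per molecular formula; every isomer element carries its
constitutional SMILES and stereocenter counts, with one nested element per
stereoisomer.  Enantiomer cross-references point at the sibling
stereoisomer id within the same isomer element.  The document validates
against the DTD shipped with the package.
"""

from __future__ import annotations

import importlib.resources
from typing import IO, Iterable

from lxml import etree

from .pipeline import IsomerRecord

__all__ = ["write_xml", "read_xml", "load_dtd", "validate_xml"]


def load_dtd() -> etree.DTD:
    ref = importlib.resources.files("molenum.data").joinpath("isomers.dtd")
    with ref.open("rb") as fh:
        return etree.DTD(fh)


def build_tree(records: Iterable[IsomerRecord]) -> etree._ElementTree:
    root = etree.Element("enumeration")
    groups: dict[str, etree._Element] = {}
    for record in records:
        group = groups.get(record.formula)
        if group is None:
            group = etree.SubElement(root, "formula", name=record.formula)
            groups[record.formula] = group
        isomer = etree.SubElement(
            group,
            "isomer",
            smiles=record.smiles,
            n_tet=str(record.n_tet),
            n_ct=str(record.n_ct),
        )
        for idx, stereo in enumerate(record.stereoisomers):
            attrs = {
                "id": str(idx),
                "smiles": stereo.smiles,
                "n_tet": str(stereo.n_tet),
                "n_ct": str(stereo.n_ct),
            }
            if stereo.enantiomer is not None:
                attrs["enantiomer"] = str(stereo.enantiomer)
            etree.SubElement(isomer, "stereoisomer", **attrs)
    return etree.ElementTree(root)


def write_xml(records: Iterable[IsomerRecord], destination: str | IO[bytes]) -> None:
    tree = build_tree(records)
    tree.write(
        destination,
        pretty_print=True,
        xml_declaration=True,
        encoding="utf-8",
    )


def validate_xml(source) -> bool:
    tree = etree.parse(source)
    return load_dtd().validate(tree)


def read_xml(source) -> list[dict]:
    """Re-parse an output document into plain dictionaries."""
    tree = etree.parse(source)
    out = []
    for formula in tree.getroot():
        for isomer in formula:
            out.append(
                {
                    "formula": formula.get("name"),
                    "smiles": isomer.get("smiles"),
                    "n_tet": int(isomer.get("n_tet")),
                    "n_ct": int(isomer.get("n_ct")),
                    "stereoisomers": [
                        {
                            "id": int(s.get("id")),
                            "smiles": s.get("smiles"),
                            "n_tet": int(s.get("n_tet")),
                            "n_ct": int(s.get("n_ct")),
                            "enantiomer": (
                                int(s.get("enantiomer"))
                                if s.get("enantiomer") is not None
                                else None
                            ),
                        }
                        for s in isomer
                    ],
                }
            )
    return out
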