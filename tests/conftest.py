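import pytest
from rdkit import Chem, RDLogger

from molenum import canonicalize, parse_smiles

RDLogger.DisableLog("rdApp.*")


def molecule(smiles: str):
    """Canonical isomer (matrix + automorphism group) built from a SMILES
    fixture string."""
    return canonicalize(parse_smiles(smiles))


def rdkit_canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"RDKit rejected {smiles!r}"
    return Chem.MolToSmiles(mol)


@pytest.fixture
def rdcanon():
    return rdkit_canonical
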