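"""Thin wrappers around the chemistry toolkit (RDKit).

Validity, canonicalization, QED and SAS are consumed from RDKit as black-box
oracles: QED is the geometric mean of eight drug-likeness properties in
[0, 1]; SAS is the fragment-based synthetic-accessibility score in roughly
[1, 10], higher meaning harder to synthesize.
"""

from __future__ import annotations

import os
import sys
from typing import Optional

from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import QED

RDLogger.DisableLog("rdApp.*")  # parse failures are an expected code path

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module, resolved via RDConfig)


def mol_from_smiles(smiles: str) -> Optional[Chem.Mol]:
    """Parse and sanitize; None when the string is not a valid molecule."""
    if not smiles:
        return None
    return Chem.MolFromSmiles(smiles)


def is_valid(smiles: str) -> bool:
    """True iff RDKit parses and sanitizes the SMILES into a molecule object."""
    return mol_from_smiles(smiles) is not None


def canonical_smiles(smiles: str) -> Optional[str]:
    """Canonical form used for molecule-identity comparisons, or None if invalid."""
    mol = mol_from_smiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def qed(smiles_or_mol) -> float:
    mol = smiles_or_mol if isinstance(smiles_or_mol, Chem.Mol) else mol_from_smiles(smiles_or_mol)
    if mol is None:
        raise ValueError(f"invalid molecule: {smiles_or_mol!r}")
    return float(QED.qed(mol))


def sas(smiles_or_mol) -> float:
    mol = smiles_or_mol if isinstance(smiles_or_mol, Chem.Mol) else mol_from_smiles(smiles_or_mol)
    if mol is None:
        raise ValueError(f"invalid molecule: {smiles_or_mol!r}")
    return float(sascorer.calculateScore(mol))
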