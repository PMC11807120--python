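"""Shared cheminformatics primitives.

One canonicalization procedure and one fingerprint routine are used everywhere
(reactant/product pairing, deduplication, uniqueness, diversity) so that string
equality of canonical SMILES is equivalent to molecule identity throughout the
package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string does not parse to a molecule."""


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"invalid SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonicalize with RDKit's default algorithm (the project-wide procedure)."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def is_valid_smiles(smiles: str) -> bool:
    return Chem.MolFromSmiles(smiles) is not None


@dataclass(frozen=True)
class FingerprintSpec:
    """Circular-fingerprint settings.

    ``diameter`` is the ECFP diameter (ECFP4 -> 4, ECFP6 -> 6); the Morgan
    radius is diameter / 2.  Bit fingerprints only (counted = False).
    """

    diameter: int = 4
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.diameter % 2 != 0:
            raise ValueError("ECFP diameter must be even")
        if self.n_bits & (self.n_bits - 1) != 0:
            raise ValueError("bit length must be a power of two")

    @property
    def radius(self) -> int:
        return self.diameter // 2


#: ECFP4/2048 — used for reactant-product pairing and the diversity metric.
ECFP4 = FingerprintSpec(diameter=4, n_bits=2048)
#: ECFP6/2048 — used for the activity-prediction reward.
ECFP6 = FingerprintSpec(diameter=6, n_bits=2048)

_GENERATORS: dict[FingerprintSpec, object] = {}


def fingerprint(smiles: str, spec: FingerprintSpec = ECFP4) -> np.ndarray:
    """Return the binary circular fingerprint as a uint8 vector."""
    gen = _GENERATORS.get(spec)
    if gen is None:
        gen = GetMorganGenerator(radius=spec.radius, fpSize=spec.n_bits)
        _GENERATORS[spec] = gen
    fp = gen.GetFingerprintAsNumPy(mol_from_smiles(smiles))
    return fp.astype(np.uint8)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity of two binary fingerprints (1.0 for two empty ones)."""
    inter = int(np.sum(a & b))
    union = int(np.sum(a | b))
    return 1.0 if union == 0 else inter / union


def heavy_atom_count(smiles: str) -> int:
    return mol_from_smiles(smiles).GetNumHeavyAtoms()


def molecular_weight(smiles: str) -> float:
    return Descriptors.MolWt(mol_from_smiles(smiles))


def murcko_scaffold(smiles: str) -> str:
    """Canonical SMILES of the Bemis-Murcko scaffold ('' for acyclic molecules)."""
    scaf = MurckoScaffold.GetScaffoldForMol(mol_from_smiles(smiles))
    return Chem.MolToSmiles(scaf)
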