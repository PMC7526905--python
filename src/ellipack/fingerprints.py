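"""Hashed circular (ECFP/Morgan) fingerprints of single molecules."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = ["Fingerprint", "compute_fingerprint"]


@dataclass(frozen=True)
class Fingerprint:
    """Binary circular fingerprint of one molecule."""

    bits: np.ndarray
    radius: int
    n_bits: int
    smiles: str

    def __post_init__(self) -> None:
        b = np.asarray(self.bits, dtype=np.uint8)
        if b.shape != (self.n_bits,) or not np.isin(b, (0, 1)).all():
            raise ValueError("fingerprint must be a binary vector of length n_bits")
        object.__setattr__(self, "bits", b)

    @property
    def n_on(self) -> int:
        return int(self.bits.sum())


@lru_cache(maxsize=8)
def _generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def compute_fingerprint(smiles: str, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """ECFP-style hashed fingerprint of a SMILES string.

    Circular atom environments up to the given bond radius are hashed into a
    fixed-length binary vector (radius 2 corresponds to ECFP4).  Deterministic
    for a fixed molecule regardless of the SMILES writing (atom numbering).
    """
    if radius < 0 or n_bits < 1:
        raise ValueError("radius must be >= 0 and n_bits >= 1")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    bits = _generator(radius, n_bits).GetFingerprintAsNumPy(mol)
    return Fingerprint(bits=bits.astype(np.uint8), radius=radius, n_bits=n_bits, smiles=smiles)
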