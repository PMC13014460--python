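"""MACCS and ECFP4 binary fingerprints and their concatenation.

The fingerprint view of a molecule is M_fp = [M_maccs | M_ecfp]: the 167-bit
MACCS structural keys (bit 0 is an unused placeholder) followed by a
2048-bit ECFP4 — a Morgan circular fingerprint of radius 2 (diameter 4)
folded to a fixed width. Both are standard RDKit featurizers; results are
cached per canonical SMILES so repeated training epochs featurize each
molecule once.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import SmilesParseError

__all__ = [
    "MACCS_LENGTH",
    "ECFP_LENGTH",
    "COMBINED_LENGTH",
    "FingerprintVector",
    "compute_maccs",
    "compute_ecfp4",
    "concat_fingerprints",
    "featurize_fingerprint",
]

MACCS_LENGTH = 167  # 166 structural keys + placeholder bit 0
ECFP_LENGTH = 2048
COMBINED_LENGTH = MACCS_LENGTH + ECFP_LENGTH


@dataclass(frozen=True)
class FingerprintVector:
    maccs: np.ndarray
    ecfp: np.ndarray
    combined: np.ndarray


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def compute_maccs(smiles: str) -> np.ndarray:
    """167-bit MACCS key vector (index 0 is the never-set placeholder)."""
    bv = MACCSkeys.GenMACCSKeys(_mol(smiles))
    out = np.zeros(MACCS_LENGTH, dtype=np.float64)
    out[list(bv.GetOnBits())] = 1.0
    return out


@lru_cache(maxsize=8)
def _morgan_generator(n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)


def compute_ecfp4(smiles: str, n_bits: int = ECFP_LENGTH) -> np.ndarray:
    """Binary ECFP4: circular environments of radius 2 folded to *n_bits*."""
    if n_bits < 1 or (n_bits & (n_bits - 1)) != 0:
        raise ValueError(f"n_bits must be a power of two, got {n_bits}")
    bv = _morgan_generator(n_bits).GetFingerprint(_mol(smiles))
    out = np.zeros(n_bits, dtype=np.float64)
    out[list(bv.GetOnBits())] = 1.0
    return out


def concat_fingerprints(maccs: np.ndarray, ecfp: np.ndarray) -> np.ndarray:
    if maccs.shape != (MACCS_LENGTH,):
        raise ValueError(f"MACCS vector must have length {MACCS_LENGTH}, got {maccs.shape}")
    if ecfp.ndim != 1 or ecfp.shape[0] != ECFP_LENGTH:
        raise ValueError(f"ECFP vector must have length {ECFP_LENGTH}, got {ecfp.shape}")
    return np.concatenate([maccs, ecfp])


@lru_cache(maxsize=100_000)
def _featurize_cached(smiles: str) -> tuple[bytes, bytes]:
    maccs = compute_maccs(smiles)
    ecfp = compute_ecfp4(smiles)
    return maccs.tobytes(), ecfp.tobytes()


def featurize_fingerprint(smiles: str) -> FingerprintVector:
    """Full fingerprint view of one molecule, cached per SMILES string."""
    mb, eb = _featurize_cached(smiles)
    maccs = np.frombuffer(mb, dtype=np.float64).copy()
    ecfp = np.frombuffer(eb, dtype=np.float64).copy()
    return FingerprintVector(maccs=maccs, ecfp=ecfp, combined=concat_fingerprints(maccs, ecfp))
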