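"""Molecule dataset I/O, SMILES canonicalization, and stratified splitting.

Datasets are flat sequences of :class:`MoleculeRecord` — one canonical SMILES
plus a binary acute-dermal-toxicity label (1 = toxic under GHS categories 1-4,
0 = non-toxic). All downstream featurization assumes canonical SMILES, so every
ingest path canonicalizes eagerly and drops rows RDKit cannot parse.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger
from sklearn.model_selection import ShuffleSplit, StratifiedShuffleSplit

logger = logging.getLogger(__name__)

# RDKit logs every rejected SMILES to stderr; invalid rows are an expected,
# counted condition here.
RDLogger.DisableLog("rdApp.error")

__all__ = [
    "MoleculeRecord",
    "Dataset",
    "DatasetSplit",
    "canonicalize_smiles",
    "read_dataset",
    "read_smiles_file",
    "write_dataset",
    "stratified_split",
    "SmilesParseError",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed by the chemistry toolkit."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: opaque id, canonical SMILES, binary toxicity label."""

    id: str
    smiles: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


class Dataset(list):
    """A list of :class:`MoleculeRecord` that remembers ingest skip counts."""

    n_skipped: int = 0


@dataclass
class DatasetSplit:
    """Seeded train/validation (and optionally test) partition of a dataset."""

    train: list[MoleculeRecord]
    validation: list[MoleculeRecord]
    test: list[MoleculeRecord] = field(default_factory=list)
    seed: int = 0


def canonicalize_smiles(smiles: str) -> str:
    """Return the RDKit-canonical form of *smiles*.

    Deterministic and idempotent. Raises :class:`SmilesParseError` for empty
    or unparseable input.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def read_dataset(
    path: str | Path,
    smiles_column: str = "smiles",
    label_column: str = "label",
    id_column: str | None = None,
    deduplicate: bool = False,
) -> Dataset:
    """Read a molecule CSV into canonical :class:`MoleculeRecord` rows.

    Rows whose SMILES fail to parse are dropped; the count is logged and kept
    on the returned object's ``n_skipped``. With ``deduplicate``, later rows
    with an already-seen canonical SMILES are dropped too (not counted as
    skips). Row ids come from *id_column* when given, from an ``id`` column
    when one exists, otherwise from the row index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if id_column is None and "id" in df.columns:
        id_column = "id"
    for col in (smiles_column, label_column):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path} (has {list(df.columns)})")
    records = Dataset()
    skipped = 0
    seen: set[str] = set()
    for i, row in df.iterrows():
        raw = str(row[smiles_column])
        try:
            canon = canonicalize_smiles(raw)
        except SmilesParseError:
            skipped += 1
            continue
        if deduplicate:
            if canon in seen:
                continue
            seen.add(canon)
        rid = str(row[id_column]) if id_column else f"{path.stem}-{i}"
        records.append(MoleculeRecord(id=rid, smiles=canon, label=int(row[label_column])))
    records.n_skipped = skipped
    if skipped:
        logger.warning("dropped %d unparseable SMILES while reading %s", skipped, path)
    if not records:
        raise ValueError(f"no valid molecule rows in {path}")
    return records


def read_smiles_file(path: str | Path) -> Dataset:
    """Read a plain ``.smi`` file: one SMILES per line, optional trailing id.

    Labels are unavailable in this format; records get label 0 and are meant
    for tokenization/prediction, not training.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = Dataset()
    skipped = 0
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        try:
            canon = canonicalize_smiles(parts[0])
        except SmilesParseError:
            skipped += 1
            continue
        rid = parts[1] if len(parts) > 1 else f"{path.stem}-{i}"
        records.append(MoleculeRecord(id=rid, smiles=canon, label=0))
    records.n_skipped = skipped
    if skipped:
        logger.warning("dropped %d unparseable SMILES while reading %s", skipped, path)
    return records


def write_dataset(
    records: Sequence[MoleculeRecord],
    path: str | Path,
    smiles_column: str = "smiles",
    label_column: str = "label",
) -> None:
    """Write records to CSV with id, smiles, and label columns."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            smiles_column: [r.smiles for r in records],
            label_column: [r.label for r in records],
        }
    )
    df.to_csv(path, index=False)


def stratified_split(
    records: Sequence[MoleculeRecord],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> DatasetSplit:
    """Split records into train/validation at *train_fraction*, stratified by label.

    Deterministic for a fixed seed. Sizes are the floor/ceil partition of the
    requested fraction; label proportions in each part stay within one record
    of the pooled proportion. Single-class input triggers a warning and a
    plain (non-stratified) shuffle split.
    """
    if not records:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = [r.label for r in records]
    if len(set(labels)) < 2:
        warnings.warn(
            "single-class dataset: falling back to a non-stratified split",
            UserWarning,
            stacklevel=2,
        )
        splitter = ShuffleSplit(n_splits=1, train_size=train_fraction, random_state=seed)
    else:
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=train_fraction, random_state=seed
        )
    try:
        train_idx, val_idx = next(splitter.split(list(range(len(records))), labels))
    except ValueError:
        # pool too small to stratify (a split side cannot hold every class)
        warnings.warn(
            "dataset too small to stratify: falling back to a plain shuffle split",
            UserWarning,
            stacklevel=2,
        )
        splitter = ShuffleSplit(n_splits=1, train_size=train_fraction, random_state=seed)
        train_idx, val_idx = next(splitter.split(list(range(len(records)))))
    train = [records[i] for i in sorted(train_idx)]
    validation = [records[i] for i in sorted(val_idx)]
    return DatasetSplit(train=train, validation=validation, seed=seed)
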