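"""Seeded synthetic SMILES datasets with substructure-driven toxicity labels.

The generator assembles molecules by concatenating small chemically valid
fragments (alkyl chains, branches, hydroxyl/carbonyl groups, benzene, chiral
bracket atoms) into linear-chain SMILES. A molecule is "toxic" when it
contains the configured toxicophore substructure (default: a trichloromethyl
group), optionally XOR-ed with a Bernoulli label-noise flip. This emulates
the structure of small, imbalanced acute-toxicity datasets — a minority
positive class driven by a recognizable substructure — without any download.

It also produces near-duplicate molecule pairs differing by the insertion of
one or two chain carbons, with discordant labels: the hard case that
motivates substructure-aware (BPE) tokenization, since long-chain homologues
can share identical folded fingerprints.

Every generated SMILES is validated with RDKit. Dataset records carry
canonical SMILES; near-duplicate pair members keep their generated string
form so the few-character edit structure of the pair is preserved verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeRecord, canonicalize_smiles

__all__ = ["SyntheticConfig", "generate_dataset", "generate_similar_pairs", "DEFAULT_FRAGMENTS"]

#: Fragments exercise all tokenizer paths: multi-char atoms (Cl in the
#: toxicophore), bracket atoms, branches, rings, and plain chains.
DEFAULT_FRAGMENTS = [
    "C",
    "CC",
    "CCC",
    "C(C)",
    "C(O)",
    "CO",
    "CN",
    "C(=O)",
    "[C@H](O)",
    "[C@@H](C)",
    "c1ccccc1",
]

#: Fragments safe to start a SMILES string with (no leading branch or
#: under-bonded bracket atom).
_STARTERS = ["C", "CC", "CCC", "CO", "CN"]


@dataclass
class SyntheticConfig:
    n: int = 1500
    positive_fraction: float = 0.3
    toxicophore: str = "C(Cl)(Cl)Cl"
    label_noise: float = 0.0
    fragment_alphabet: list[str] = field(default_factory=lambda: list(DEFAULT_FRAGMENTS))
    max_heavy_atoms: int = 40
    min_fragments: int = 2
    max_fragments: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        tox = Chem.MolFromSmiles("C" + self.toxicophore)
        if tox is None:
            raise ValueError(f"toxicophore is not a valid SMILES suffix: {self.toxicophore!r}")
        if tox.GetNumHeavyAtoms() > self.max_heavy_atoms:
            raise ValueError("toxicophore larger than max_heavy_atoms")


def _backbone(rng: np.random.Generator, config: SyntheticConfig) -> str:
    n_frag = int(rng.integers(config.min_fragments, config.max_fragments + 1))
    parts = [_STARTERS[rng.integers(len(_STARTERS))]]
    for _ in range(n_frag - 1):
        parts.append(config.fragment_alphabet[rng.integers(len(config.fragment_alphabet))])
    return "".join(parts)


def _valid_mol(smiles: str, max_heavy: int) -> Chem.Mol | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() > max_heavy:
        return None
    return mol


def generate_dataset(config: SyntheticConfig) -> list[MoleculeRecord]:
    """Generate ``config.n`` records with exactly round(n * positive_fraction)
    toxicophore-containing molecules; labels are presence XOR a seeded
    Bernoulli(label_noise) flip."""
    rng = np.random.default_rng(config.seed)
    pattern = Chem.MolFromSmarts(config.toxicophore)
    n_pos = round(config.n * config.positive_fraction)
    records: list[MoleculeRecord] = []
    for i in range(config.n):
        wants_toxicophore = i < n_pos
        for _attempt in range(200):
            smiles = _backbone(rng, config)
            if wants_toxicophore:
                smiles += config.toxicophore
            mol = _valid_mol(smiles, config.max_heavy_atoms)
            if mol is None:
                continue
            if bool(mol.HasSubstructMatch(pattern)) == wants_toxicophore:
                break
        else:
            raise RuntimeError("could not generate a valid molecule; check the fragment alphabet")
        label = int(wants_toxicophore)
        if config.label_noise > 0 and rng.random() < config.label_noise:
            label = 1 - label
        records.append(
            MoleculeRecord(id=f"syn-{i:05d}", smiles=canonicalize_smiles(smiles), label=label)
        )
    order = rng.permutation(config.n)
    return [records[j] for j in order]


def _insertion_points(smiles: str) -> list[int]:
    """Indices i where a 'C' can be inserted after smiles[i] without breaking
    a two-letter element, a bracket expression, or a ring-bond digit."""
    points = []
    depth = 0
    for i, ch in enumerate(smiles):
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        if ch == "C" and depth == 0:
            nxt = smiles[i + 1] if i + 1 < len(smiles) else ""
            if nxt not in ("l",) and not nxt.isdigit():
                points.append(i)
    return points


def generate_similar_pairs(
    config: SyntheticConfig, n_pairs: int
) -> list[tuple[MoleculeRecord, MoleculeRecord]]:
    """Near-duplicate pairs: member B is member A with 1-2 extra chain
    carbons; labels are discordant (1, 0) by construction.

    About half the pairs are long plain carbon chains, for which the homologue
    members fold to identical MACCS/ECFP4 fingerprints — the case where only
    token-level views can still discriminate.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(config.seed + 1)
    pairs: list[tuple[MoleculeRecord, MoleculeRecord]] = []
    for i in range(n_pairs):
        for _attempt in range(200):
            if rng.random() < 0.5:
                base = "C" * int(rng.integers(8, 15))
            else:
                base = canonicalize_smiles(_backbone(rng, config))
            points = _insertion_points(base)
            if not points:
                continue
            cut = points[rng.integers(len(points))] + 1
            n_insert = int(rng.integers(1, 3))
            variant = base[:cut] + "C" * n_insert + base[cut:]
            if _valid_mol(variant, config.max_heavy_atoms + 2) is not None:
                break
        else:
            raise RuntimeError("could not generate a valid near-duplicate pair")
        pairs.append(
            (
                MoleculeRecord(id=f"pair-{i:04d}-a", smiles=base, label=1),
                MoleculeRecord(id=f"pair-{i:04d}-b", smiles=variant, label=0),
            )
        )
    return pairs
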