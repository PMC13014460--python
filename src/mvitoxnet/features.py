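"""Corpus-fitted featurizer: turns SMILES into the four model inputs.

A :class:`Featurizer` is fitted on the training corpus only. It builds the
character- and atom-level vocabularies, trains the BPE merge table (or
accepts a pretrained one), and afterwards maps any SMILES to the three
fixed-length id sequences plus the 2215-bit fingerprint vector. Tokens unseen
at fit time encode to the unknown id.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from . import tokenizers as tok
from .fingerprints import featurize_fingerprint

__all__ = ["Featurizer", "DEFAULT_BPE_TARGET_SIZE"]

#: Pretrained-vocabulary size used by the reference method; small corpora
#: saturate far below this (merging stops when no pair repeats).
DEFAULT_BPE_TARGET_SIZE = 498


class Featurizer:
    def __init__(
        self,
        max_lengths: dict[str, int] | None = None,
        bpe_target_size: int = DEFAULT_BPE_TARGET_SIZE,
        merges: tok.BPEMergeTable | None = None,
    ) -> None:
        self.max_lengths = dict(max_lengths or tok.DEFAULT_MAX_LENGTHS)
        self.bpe_target_size = bpe_target_size
        self.merges = merges
        self.vocabs: dict[str, tok.Vocabulary] | None = None

    @property
    def is_fitted(self) -> bool:
        return self.vocabs is not None

    def vocab_sizes(self) -> dict[str, int]:
        if not self.is_fitted:
            raise RuntimeError("featurizer is not fitted")
        return {view: v.size for view, v in self.vocabs.items()}

    def fit(self, corpus: Sequence[str]) -> "Featurizer":
        """Build vocabularies (and the merge table, unless provided) from *corpus*."""
        if not corpus:
            raise ValueError("empty corpus")
        if self.merges is None:
            alphabet = {t for s in corpus for t in tok.tokenize_atom(s).tokens}
            target = max(self.bpe_target_size, len(alphabet) + 1)
            self.merges = tok.train_bpe(corpus, target)
        self.vocabs = {
            view: tok.build_vocabulary(
                [tok.tokenize(s, view, self.merges).tokens for s in corpus]
            )
            for view in ("char", "atom", "bpe")
        }
        return self

    def transform(self, smiles: Sequence[str]) -> dict[str, np.ndarray]:
        """Id matrices per view plus the fingerprint matrix for a SMILES batch."""
        if not self.is_fitted:
            raise RuntimeError("featurizer is not fitted")
        out: dict[str, np.ndarray] = {}
        for view in ("char", "atom", "bpe"):
            L = self.max_lengths[view]
            ids = np.empty((len(smiles), L), dtype=np.int64)
            for i, s in enumerate(smiles):
                seq = tok.tokenize(s, view, self.merges)
                ids[i] = tok.encode(seq, self.vocabs[view], L).ids
            out[view] = ids
        out["fp"] = np.stack([featurize_fingerprint(s).combined for s in smiles])
        return out

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for view, vocab in (self.vocabs or {}).items():
            tok.save_vocab(vocab, d / f"{view}_vocab.txt")
        if self.merges is not None:
            tok.save_merges(self.merges, d / "merges.txt")
        meta = {"max_lengths": self.max_lengths, "bpe_target_size": self.bpe_target_size}
        (d / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "Featurizer":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        fz = cls(max_lengths=meta["max_lengths"], bpe_target_size=meta["bpe_target_size"])
        fz.merges = tok.load_merges(d / "merges.txt")
        fz.vocabs = {
            view: tok.load_vocab(d / f"{view}_vocab.txt") for view in ("char", "atom", "bpe")
        }
        return fz
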