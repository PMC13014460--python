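"""Three SMILES views — character, atom, and byte-pair-encoding token streams.

A SMILES string is tokenized three ways:

* **char** — one token per character.
* **atom** — chemically meaningful units: bracket expressions ``[...]``,
  two-letter organic-subset halogens ``Cl``/``Br``, and ring-bond escapes
  ``%nn`` are single tokens; everything else is one character.
* **bpe** — atom-level tokens iteratively merged by a rank-ordered merge
  table learned from a corpus (most frequent adjacent pair first), exposing
  substructure units such as ``[C@H](O)``.

All three views reconstruct the input exactly when their tokens are
concatenated, which is the core invariant the encoders rely on.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PAD_TOKEN",
    "UNK_TOKEN",
    "PAD_ID",
    "UNK_ID",
    "TokenSequence",
    "Vocabulary",
    "BPEMergeTable",
    "TokenizationError",
    "tokenize_char",
    "tokenize_atom",
    "tokenize_bpe",
    "tokenize",
    "train_bpe",
    "encode",
    "build_vocabulary",
    "save_vocab",
    "load_vocab",
    "save_merges",
    "load_merges",
    "DEFAULT_MAX_LENGTHS",
]

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
PAD_ID = 0
UNK_ID = 1

#: Maximum encoded lengths per view: character-level SMILES are the longest
#: streams, BPE the shortest.
DEFAULT_MAX_LENGTHS = {"char": 80, "atom": 60, "bpe": 40}

# Bracket atoms, two-letter halogens, ring-bond escapes; then any single char.
_ATOM_RE = re.compile(r"\[[^\[\]]+\]|Br|Cl|%\d{2}|.")


class TokenizationError(ValueError):
    pass


@dataclass
class TokenSequence:
    """Tokens for one SMILES under one view, optionally with integer ids."""

    view: str
    tokens: list[str]
    ids: list[int] | None = None

    def text(self) -> str:
        return "".join(self.tokens)


@dataclass
class Vocabulary:
    """Bijective token <-> id map with reserved pad (0) and unknown (1) ids."""

    token_to_id: dict[str, int]

    def __post_init__(self) -> None:
        if self.token_to_id.get(PAD_TOKEN) != PAD_ID or self.token_to_id.get(UNK_TOKEN) != UNK_ID:
            raise ValueError("vocabulary must reserve <pad>=0 and <unk>=1")
        ids = sorted(self.token_to_id.values())
        if ids != list(range(len(ids))):
            raise ValueError("vocabulary ids must be contiguous from 0")

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    def id_of(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def tokens(self) -> list[str]:
        inv = {i: t for t, i in self.token_to_id.items()}
        return [inv[i] for i in range(self.size)]


@dataclass
class BPEMergeTable:
    """Rank-ordered adjacent-pair merges over atom-level base tokens."""

    merges: list[tuple[str, str]] = field(default_factory=list)
    target_size: int | None = None

    def merged_tokens(self) -> list[str]:
        return [a + b for a, b in self.merges]

    def ranks(self) -> dict[tuple[str, str], int]:
        return {pair: rank for rank, pair in enumerate(self.merges)}


def tokenize_char(smiles: str) -> TokenSequence:
    """One token per character."""
    if not smiles:
        raise TokenizationError("empty SMILES string")
    return TokenSequence(view="char", tokens=list(smiles))


def tokenize_atom(smiles: str) -> TokenSequence:
    """Atom-level units: ``[...]``, ``Cl``/``Br``, ``%nn`` as single tokens."""
    if not smiles:
        raise TokenizationError("empty SMILES string")
    tokens = _ATOM_RE.findall(smiles)
    joined = "".join(tokens)
    if joined != smiles or any(t in "[]" for t in tokens):
        raise TokenizationError(f"unbalanced bracket expression in {smiles!r}")
    return TokenSequence(view="atom", tokens=tokens)


def _apply_merges(tokens: list[str], ranks: dict[tuple[str, str], int]) -> list[str]:
    """Apply merges in rank order until no adjacent pair is mergeable."""
    tokens = list(tokens)
    while len(tokens) > 1:
        best_rank = None
        for pair in zip(tokens, tokens[1:]):
            r = ranks.get(pair)
            if r is not None and (best_rank is None or r < best_rank):
                best_rank = r
                best_pair = pair
        if best_rank is None:
            break
        merged: list[str] = []
        i = 0
        while i < len(tokens):
            if (
                i + 1 < len(tokens)
                and (tokens[i], tokens[i + 1]) == best_pair
            ):
                merged.append(tokens[i] + tokens[i + 1])
                i += 2
            else:
                merged.append(tokens[i])
                i += 1
        tokens = merged
    return tokens


def tokenize_bpe(smiles: str, merges: BPEMergeTable) -> TokenSequence:
    """Atom-level tokenize, then apply the merge table exhaustively."""
    base = tokenize_atom(smiles)
    return TokenSequence(view="bpe", tokens=_apply_merges(base.tokens, merges.ranks()))


def tokenize(smiles: str, view: str, merges: BPEMergeTable | None = None) -> TokenSequence:
    """Dispatch to one of the three views by name."""
    if view == "char":
        return tokenize_char(smiles)
    if view == "atom":
        return tokenize_atom(smiles)
    if view == "bpe":
        return tokenize_bpe(smiles, merges or BPEMergeTable())
    raise ValueError(f"unknown view {view!r} (expected char, atom, or bpe)")


def train_bpe(corpus: Sequence[str], target_size: int) -> BPEMergeTable:
    """Learn a merge table from a SMILES corpus.

    Repeatedly merges the most frequent adjacent token pair (base units are
    atom-level tokens) until the derived vocabulary — base alphabet plus
    merged tokens — reaches *target_size*, or no pair occurs at least twice.
    Ties break toward the lexicographically smallest (left, right) pair, which
    makes training deterministic given the corpus.
    """
    if not corpus:
        raise ValueError("empty corpus")
    sequences = [tokenize_atom(s).tokens for s in corpus]
    alphabet = {t for seq in sequences for t in seq}
    if target_size <= len(alphabet):
        raise ValueError(
            f"target_size {target_size} must exceed the base alphabet size {len(alphabet)}"
        )
    merges: list[tuple[str, str]] = []
    vocab_size = len(alphabet)
    while vocab_size < target_size:
        counts: Counter[tuple[str, str]] = Counter()
        for seq in sequences:
            counts.update(zip(seq, seq[1:]))
        if not counts:
            break
        best = min(counts, key=lambda p: (-counts[p], p))
        if counts[best] < 2:
            break
        merges.append(best)
        ranks = {best: 0}
        sequences = [_apply_merges(seq, ranks) for seq in sequences]
        vocab_size += 1
    return BPEMergeTable(merges=merges, target_size=target_size)


def build_vocabulary(token_lists: Iterable[Sequence[str]]) -> Vocabulary:
    """Vocabulary over all tokens seen, sorted lexicographically after pad/unk."""
    content = sorted({t for toks in token_lists for t in toks})
    mapping = {PAD_TOKEN: PAD_ID, UNK_TOKEN: UNK_ID}
    for i, tok in enumerate(content, start=2):
        mapping[tok] = i
    return Vocabulary(mapping)


def encode(seq: TokenSequence, vocab: Vocabulary, max_length: int) -> TokenSequence:
    """Truncate to *max_length*, map to ids, right-pad with the pad id."""
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    tokens = seq.tokens[:max_length]
    ids = [vocab.id_of(t) for t in tokens]
    ids.extend([PAD_ID] * (max_length - len(ids)))
    return TokenSequence(view=seq.view, tokens=tokens, ids=ids)


def save_vocab(vocab: Vocabulary, path: str | Path) -> None:
    """One token per line; line number - 1 is the id; first lines are pad/unk."""
    Path(path).write_text("\n".join(vocab.tokens()) + "\n", encoding="utf-8")


def load_vocab(path: str | Path) -> Vocabulary:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    mapping: dict[str, int] = {}
    for i, tok in enumerate(lines):
        if tok in mapping:
            raise ValueError(f"{path}: duplicate token {tok!r} at line {i + 1}")
        mapping[tok] = i
    return Vocabulary(mapping)


def save_merges(table: BPEMergeTable, path: str | Path) -> None:
    """One merge per line as two space-separated tokens, file order = rank."""
    lines = [f"{a} {b}" for a, b in table.merges]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def load_merges(path: str | Path) -> BPEMergeTable:
    merges: list[tuple[str, str]] = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: line {i + 1} is not a two-token merge: {line!r}")
        merges.append((parts[0], parts[1]))
    return BPEMergeTable(merges=merges)
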