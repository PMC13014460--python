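"""Training loop, per-epoch checkpointing, and weighted model averaging (WMA).

Training minimizes binary cross-entropy with Adam on seeded, shuffled
minibatches. After every epoch the validation AUPRC is computed (AUPRC is the
model-selection metric: the datasets are small and positive-minority, so
precision-recall behaviour matters more than accuracy) and a deep parameter
snapshot is stored.

WMA then combines the top-K (default 3) checkpoints by validation AUPRC into
a single inference model:

    W_final = (1 - 2*kappa) * W1 + kappa * (W2 + W3)

with W1 the best checkpoint. kappa in [0, 0.4] keeps every weight
non-negative and the weights always sum to one; kappa = 0 reduces to plain
best-checkpoint selection.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import metrics
from .chem_io import DatasetSplit, MoleculeRecord, stratified_split
from .features import Featurizer
from .network import (
    ModelConfig,
    forward,
    forward_backward,
    init_parameters,
    load_checkpoint,
    save_checkpoint,
)
from .nn import AdamOptimizer

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "Checkpoint",
    "CheckpointStore",
    "train",
    "select_topk",
    "weighted_average",
    "predict_smiles",
    "run_experiment",
]


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-5
    batch_size: int = 64
    epochs: int = 50
    kappa: float = 0.2
    top_k: int = 3
    seed: int = 0
    subsequent_only: bool = False  # restrict W2/W3 to epochs after the best

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 0.4:
            raise ValueError("kappa must lie in [0, 0.4] so the top weight stays positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class Checkpoint:
    params: dict[str, np.ndarray]
    epoch: int
    val_auprc: float


@dataclass
class CheckpointStore:
    """One parameter snapshot per trained epoch, with its validation AUPRC."""

    checkpoints: list[Checkpoint]
    config: ModelConfig
    featurizer: Featurizer | None = None
    history: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.checkpoints)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        lines = ["epoch\tval_auprc\tfile"]
        for ck in self.checkpoints:
            fname = f"epoch_{ck.epoch:03d}.npz"
            save_checkpoint(d / fname, ck.params, self.config, ck.epoch, ck.val_auprc)
            lines.append(f"{ck.epoch}\t{ck.val_auprc:.17g}\t{fname}")
        (d / "manifest.tsv").write_text("\n".join(lines) + "\n")
        if self.featurizer is not None:
            self.featurizer.save(d / "featurizer")

    @classmethod
    def load(cls, directory: str | Path) -> "CheckpointStore":
        d = Path(directory)
        rows = (d / "manifest.tsv").read_text().splitlines()[1:]
        checkpoints = []
        config = None
        for row in rows:
            epoch_s, auprc_s, fname = row.split("\t")
            params, config, epoch, val_auprc = load_checkpoint(d / fname)
            checkpoints.append(
                Checkpoint(params=params, epoch=int(epoch_s), val_auprc=float(auprc_s))
            )
        if config is None:
            raise ValueError(f"empty checkpoint manifest in {d}")
        featurizer = Featurizer.load(d / "featurizer") if (d / "featurizer").exists() else None
        return cls(checkpoints=checkpoints, config=config, featurizer=featurizer)


def _predict_features(
    features: Mapping[str, np.ndarray],
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    batch_size: int = 256,
) -> np.ndarray:
    n = features["fp"].shape[0]
    probs = np.empty(n)
    for lo in range(0, n, batch_size):
        batch = {k: v[lo : lo + batch_size] for k, v in features.items()}
        probs[lo : lo + batch_size] = forward(batch, params, config)
    return probs


def train(
    split: DatasetSplit,
    training_config: TrainingConfig,
    model_config: ModelConfig | None = None,
    featurizer: Featurizer | None = None,
    model_overrides: Mapping | None = None,
) -> CheckpointStore:
    """Train on *split* and return one checkpoint per epoch.

    The featurizer (vocabularies, BPE merges) is fitted on the training
    SMILES only, unless one is supplied. Fully deterministic for a fixed
    seed: initialization and minibatch shuffling both derive from
    ``training_config.seed``.
    """
    if not split.train or not split.validation:
        raise ValueError("train and validation sets must both be non-empty")
    train_smiles = [r.smiles for r in split.train]
    if featurizer is None:
        featurizer = Featurizer().fit(train_smiles)
    if model_config is None:
        model_config = ModelConfig(
            vocab_sizes=featurizer.vocab_sizes(),
            max_lengths=dict(featurizer.max_lengths),
            **dict(model_overrides or {}),
        )
    feats_train = featurizer.transform(train_smiles)
    y_train = np.array([r.label for r in split.train], dtype=np.float64)
    feats_val = featurizer.transform([r.smiles for r in split.validation])
    y_val = np.array([r.label for r in split.validation], dtype=np.float64)

    rng = np.random.default_rng(training_config.seed)
    params = init_parameters(model_config, seed=int(rng.integers(2**31)))
    optimizer = AdamOptimizer(list(params), learning_rate=training_config.learning_rate)

    checkpoints: list[Checkpoint] = []
    history: list[dict] = []
    n = len(split.train)
    for epoch in range(1, training_config.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, training_config.batch_size):
            idx = order[lo : lo + training_config.batch_size]
            batch = {k: v[idx] for k, v in feats_train.items()}
            loss, grads = forward_backward(batch, y_train[idx], params, model_config)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} (lr="
                    f"{training_config.learning_rate}); aborting"
                )
            optimizer.step(params, grads)
            epoch_loss += loss * len(idx)
        epoch_loss /= n
        val_probs = _predict_features(feats_val, params, model_config)
        val_auprc = metrics.auprc(y_val, val_probs)
        checkpoints.append(
            Checkpoint(params=copy.deepcopy(params), epoch=epoch, val_auprc=float(val_auprc))
        )
        history.append({"epoch": epoch, "train_loss": epoch_loss, "val_auprc": float(val_auprc)})
        logger.info("epoch %d: train_loss=%.5f val_auprc=%.4f", epoch, epoch_loss, val_auprc)
    return CheckpointStore(
        checkpoints=checkpoints, config=model_config, featurizer=featurizer, history=history
    )


def select_topk(
    store: CheckpointStore, k: int = 3, subsequent_only: bool = False
) -> list[Checkpoint]:
    """The k checkpoints with highest validation AUPRC, best first.

    Ties break toward the *later* epoch: AUPRC is threshold-free, so on a
    small validation set many checkpoints can tie exactly (often at 1.0 once
    the ranking is perfect), and among equally-ranked checkpoints the
    more-trained one has lower training loss and better-calibrated
    probabilities. With ``subsequent_only`` the runner-ups are restricted to
    epochs after the best one (an alternative reading of "next best from
    subsequent epochs"); the default considers all epochs.
    """
    if not store.checkpoints:
        raise ValueError("empty checkpoint store")
    ranked = sorted(store.checkpoints, key=lambda c: (-c.val_auprc, -c.epoch))
    best = ranked[0]
    if subsequent_only:
        pool = [c for c in ranked[1:] if c.epoch > best.epoch]
    else:
        pool = ranked[1:]
    return [best] + pool[: k - 1]


def weighted_average(top: Sequence[Checkpoint], kappa: float) -> dict[str, np.ndarray]:
    """Combine checkpoints as (1-2k)*W1 + k*W2 + k*W3, elementwise.

    With fewer than three checkpoints the same weight profile is
    renormalized to sum to one (two checkpoints: (1-2k)/(1-k), k/(1-k); one:
    identity). The result carries no epoch/AUPRC metadata — it is a fresh
    inference model.
    """
    if not top:
        raise ValueError("no checkpoints to average")
    if not 0.0 <= kappa <= 0.4:
        raise ValueError("kappa must lie in [0, 0.4]")
    schema = {name: p.shape for name, p in top[0].params.items()}
    for ck in top[1:]:
        if {n: p.shape for n, p in ck.params.items()} != schema:
            raise ValueError("checkpoints have mismatched parameter schemas")
    weights = np.array([1.0 - 2.0 * kappa, kappa, kappa][: len(top)])
    weights = weights / weights.sum()
    out: dict[str, np.ndarray] = {}
    for name in schema:
        acc = weights[0] * top[0].params[name]
        for w, ck in zip(weights[1:], top[1:]):
            acc = acc + w * ck.params[name]
        out[name] = acc
    return out


def predict_smiles(
    smiles: Sequence[str],
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    featurizer: Featurizer,
    batch_size: int = 256,
) -> np.ndarray:
    """Toxicity probabilities for a batch of (canonical) SMILES."""
    return _predict_features(featurizer.transform(smiles), params, config, batch_size)


def run_experiment(
    pool: Sequence[MoleculeRecord],
    test: Sequence[MoleculeRecord],
    training_config: TrainingConfig,
    seeds: Sequence[int] = tuple(range(10)),
    model_overrides: Mapping | None = None,
    threshold: float = 0.5,
) -> tuple[dict[int, metrics.EvaluationReport], metrics.EvaluationReport]:
    """Split/train/average/evaluate once per seed; report per-seed and mean metrics.

    The test set is supplied separately (external evaluation), never carved
    from the pool.
    """
    if not test:
        raise ValueError("an external test set is required")
    y_test = [r.label for r in test]
    reports: dict[int, metrics.EvaluationReport] = {}
    for seed in seeds:
        split = stratified_split(pool, seed=seed)
        tc = TrainingConfig(**{**asdict(training_config), "seed": seed})
        store = train(split, tc, model_overrides=model_overrides)
        top = select_topk(store, tc.top_k, tc.subsequent_only)
        final = weighted_average(top, tc.kappa)
        probs = predict_smiles([r.smiles for r in test], final, store.config, store.featurizer)
        reports[seed] = metrics.evaluate_all(y_test, probs, threshold)
    return reports, metrics.mean_report(list(reports.values()))
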