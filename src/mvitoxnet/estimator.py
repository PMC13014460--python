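"""scikit-learn-style estimator wrapping the full multiview pipeline.

``MVIToxNetClassifier.fit(X, y)`` takes raw SMILES strings and binary
labels, fits the featurizer (vocabularies + BPE merges) on the internal
training portion, trains the multiview CNN with Adam/BCE, and collapses the
top-K validation-AUPRC checkpoints into a single inference model by weighted
model averaging. The estimator composes with sklearn model selection and
pipelines (clone, get_params/set_params, predict_proba).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .chem_io import MoleculeRecord, canonicalize_smiles, stratified_split
from .features import DEFAULT_BPE_TARGET_SIZE, Featurizer
from .training import (
    TrainingConfig,
    predict_smiles,
    select_topk,
    train,
    weighted_average,
)

__all__ = ["MVIToxNetClassifier"]


class MVIToxNetClassifier(ClassifierMixin, BaseEstimator):
    """Multiview SMILES + fingerprint toxicity classifier with WMA ensembling.

    Parameters mirror the method's published settings: fusion weights
    ``alpha``/``beta`` (0.1), max sequence lengths 80/60/40 for the
    char/atom/BPE views, Adam at ``learning_rate`` with ``batch_size`` 64
    over ``epochs`` 50, and WMA over the ``top_k`` checkpoints with weight
    ``kappa``. Layer widths are free choices (see package docs) and default
    to 128/128/128/512.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray of shape (2,)
    featurizer_ : fitted :class:`~mvitoxnet.features.Featurizer`
    store_ : per-epoch :class:`~mvitoxnet.training.CheckpointStore`
    params_ : the averaged inference parameter map (W_final)
    config_ : the resolved :class:`~mvitoxnet.network.ModelConfig`
    """

    def __init__(
        self,
        alpha: float = 0.1,
        beta: float = 0.1,
        embed_dim: int = 128,
        conv_channels: int = 128,
        repr_dim: int = 128,
        fc_hidden: int = 512,
        kernel_size: int = 3,
        max_len_char: int = 80,
        max_len_atom: int = 60,
        max_len_bpe: int = 40,
        bpe_target_size: int = DEFAULT_BPE_TARGET_SIZE,
        learning_rate: float = 1e-5,
        batch_size: int = 64,
        epochs: int = 50,
        kappa: float = 0.2,
        top_k: int = 3,
        subsequent_only: bool = False,
        val_fraction: float = 0.2,
        threshold: float = 0.5,
        random_state: int = 0,
    ) -> None:
        self.alpha = alpha
        self.beta = beta
        self.embed_dim = embed_dim
        self.conv_channels = conv_channels
        self.repr_dim = repr_dim
        self.fc_hidden = fc_hidden
        self.kernel_size = kernel_size
        self.max_len_char = max_len_char
        self.max_len_atom = max_len_atom
        self.max_len_bpe = max_len_bpe
        self.bpe_target_size = bpe_target_size
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.kappa = kappa
        self.top_k = top_k
        self.subsequent_only = subsequent_only
        self.val_fraction = val_fraction
        self.threshold = threshold
        self.random_state = random_state

    # -- sklearn plumbing --------------------------------------------------

    def _max_lengths(self) -> dict[str, int]:
        return {"char": self.max_len_char, "atom": self.max_len_atom, "bpe": self.max_len_bpe}

    def fit(self, X, y) -> "MVIToxNetClassifier":
        """Fit on SMILES strings *X* and binary labels *y*."""
        smiles = [canonicalize_smiles(s) for s in X]
        y = np.asarray(y, dtype=np.int64)
        if y.shape != (len(smiles),):
            raise ValueError("X and y length mismatch")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        records = [
            MoleculeRecord(id=f"fit-{i}", smiles=s, label=int(lab))
            for i, (s, lab) in enumerate(zip(smiles, y))
        ]
        split = stratified_split(
            records, train_fraction=1.0 - self.val_fraction, seed=self.random_state
        )
        featurizer = Featurizer(
            max_lengths=self._max_lengths(), bpe_target_size=self.bpe_target_size
        ).fit([r.smiles for r in split.train])
        training_config = TrainingConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            kappa=self.kappa,
            top_k=self.top_k,
            seed=self.random_state,
            subsequent_only=self.subsequent_only,
        )
        store = train(
            split,
            training_config,
            featurizer=featurizer,
            model_overrides={
                "alpha": self.alpha,
                "beta": self.beta,
                "embed_dim": self.embed_dim,
                "conv_channels": self.conv_channels,
                "repr_dim": self.repr_dim,
                "fc_hidden": self.fc_hidden,
                "kernel_size": self.kernel_size,
            },
        )
        top = select_topk(store, self.top_k, self.subsequent_only)
        self.params_ = weighted_average(top, self.kappa)
        self.store_ = store
        self.featurizer_ = featurizer
        self.config_ = store.config
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        smiles = [canonicalize_smiles(s) for s in X]
        p = predict_smiles(smiles, self.params_, self.config_, self.featurizer_)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(np.int64)
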