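"""The multiview forward computation and its gradients.

Architecture (all widths configurable):

* fingerprint encoder — two fully connected layers over the 2215-bit
  MACCS+ECFP4 vector, Swish after the hidden layer: ``R_fp = FC(M_fp)``.
* three sequence encoders (char / atom / bpe) — embedding lookup, two 1-D
  convolutions (kernel 3, Softplus after each), then global max pooling
  masked to non-pad positions: ``R_view = MaxPool(CNN(M_view))``.
* weighted fusion — ``R = R_atom + alpha * (R_char + R_bpe) + beta * R_fp``;
  the atom view is the primary sequence signal, char/BPE and fingerprints are
  down-weighted auxiliaries (alpha = beta = 0.1 by default).
* decoder — one linear layer to a single logit, squashed by a sigmoid so the
  output is a probability suitable for binary cross-entropy.

Parameters live in a flat name -> float64-array dict whose schema is fully
determined by :class:`ModelConfig` — the property that makes per-epoch
checkpoints elementwise combinable for weighted model averaging. There is no
dropout or batch normalization, so outputs are independent of batch
composition and parameter averaging is well defined.

The pad embedding row is pinned at zero and max pooling is masked to non-pad
positions, which together make representations invariant to appending pad
tokens (zero 'same' conv padding then acts exactly like more pad tokens).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from . import nn
from .fingerprints import COMBINED_LENGTH
from .tokenizers import DEFAULT_MAX_LENGTHS, PAD_ID

__all__ = [
    "VIEWS",
    "ModelConfig",
    "init_parameters",
    "parameter_schema",
    "encode_fingerprint",
    "encode_sequence",
    "fuse",
    "decode",
    "forward",
    "forward_backward",
    "save_checkpoint",
    "load_checkpoint",
]

VIEWS = ("char", "atom", "bpe")


@dataclass
class ModelConfig:
    """Hyperparameters of the multiview network.

    ``alpha`` and ``beta`` are the fusion weights for the auxiliary
    char/BPE sequence views and the fingerprint view. All encoder outputs
    share ``repr_dim`` because fusion is by summation.
    """

    vocab_sizes: dict[str, int]
    alpha: float = 0.1
    beta: float = 0.1
    embed_dim: int = 128
    conv_channels: int = 128
    repr_dim: int = 128
    fc_hidden: int = 512
    kernel_size: int = 3
    fp_dim: int = COMBINED_LENGTH
    max_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MAX_LENGTHS))

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        for name in ("embed_dim", "conv_channels", "repr_dim", "fc_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not np.isfinite(self.alpha) or not np.isfinite(self.beta):
            raise ValueError("alpha and beta must be finite")
        missing = [v for v in VIEWS if v not in self.vocab_sizes]
        if missing:
            raise ValueError(f"vocab_sizes missing views: {missing}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        return cls(**dict(d))


def parameter_schema(config: ModelConfig) -> dict[str, tuple[int, ...]]:
    """Name -> shape map of every trainable parameter, fixed by the config."""
    E, C, R, H, k = (
        config.embed_dim,
        config.conv_channels,
        config.repr_dim,
        config.fc_hidden,
        config.kernel_size,
    )
    schema: dict[str, tuple[int, ...]] = {}
    for view in VIEWS:
        V = config.vocab_sizes[view]
        schema[f"emb_{view}"] = (V, E)
        schema[f"conv1_{view}_W"] = (C, E, k)
        schema[f"conv1_{view}_b"] = (C,)
        schema[f"conv2_{view}_W"] = (R, C, k)
        schema[f"conv2_{view}_b"] = (R,)
    schema["fp_W1"] = (config.fp_dim, H)
    schema["fp_b1"] = (H,)
    schema["fp_W2"] = (H, R)
    schema["fp_b2"] = (R,)
    schema["dec_W"] = (R,)
    schema["dec_b"] = (1,)
    return schema


def init_parameters(config: ModelConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Seeded initialization; the pad embedding row is pinned at zero."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    for name, shape in parameter_schema(config).items():
        if name.startswith("emb_"):
            params[name] = rng.normal(0.0, 0.1, shape)
            params[name][PAD_ID] = 0.0
        elif name.endswith("_b") or name in ("fp_b1", "fp_b2", "dec_b"):
            params[name] = np.zeros(shape)
        else:
            fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else shape[0]
            bound = np.sqrt(1.0 / fan_in)
            params[name] = rng.uniform(-bound, bound, shape)
    return params


# ---------------------------------------------------------------------------
# forward pieces (batched; single-vector convenience wrappers at the bottom)
# ---------------------------------------------------------------------------


def _encode_fp_batch(fp: np.ndarray, params: Mapping[str, np.ndarray], cache: dict | None = None):
    z1 = fp @ params["fp_W1"] + params["fp_b1"]
    a1 = nn.swish(z1)
    r = a1 @ params["fp_W2"] + params["fp_b2"]
    if cache is not None:
        cache.update(fp_in=fp, fp_z1=z1, fp_a1=a1)
    return r


def _encode_seq_batch(
    ids: np.ndarray,
    params: Mapping[str, np.ndarray],
    view: str,
    cache: dict | None = None,
) -> np.ndarray:
    emb = params[f"emb_{view}"]
    if ids.max(initial=0) >= emb.shape[0]:
        raise ValueError(f"token id out of range for view {view!r}")
    mask = ids != PAD_ID
    # all-pad rows: fall back to treating every position as content
    empty = ~mask.any(axis=1)
    if empty.any():
        mask = mask.copy()
        mask[empty] = True
    x = emb[ids]  # (B, L, E)
    z1 = nn.conv1d_same(x, params[f"conv1_{view}_W"], params[f"conv1_{view}_b"])
    # masked convolution stack: activations at pad positions are zeroed so the
    # second conv sees the same boundary context as zero 'same' padding —
    # this is what makes representations invariant to appended pad tokens
    a1 = nn.softplus(z1) * mask[:, :, None]
    z2 = nn.conv1d_same(a1, params[f"conv2_{view}_W"], params[f"conv2_{view}_b"])
    h = nn.softplus(z2)  # (B, L, R)
    hm = np.where(mask[:, :, None], h, -np.inf)
    argmax = hm.argmax(axis=1)  # (B, R)
    pooled = np.take_along_axis(h, argmax[:, None, :], axis=1)[:, 0, :]
    if cache is not None:
        cache.update(
            {
                f"{view}_ids": ids,
                f"{view}_x": x,
                f"{view}_z1": z1,
                f"{view}_a1": a1,
                f"{view}_z2": z2,
                f"{view}_mask": mask,
                f"{view}_argmax": argmax,
            }
        )
    return pooled


def fuse(
    r_atom: np.ndarray,
    r_char: np.ndarray,
    r_bpe: np.ndarray,
    r_fp: np.ndarray,
    alpha: float,
    beta: float,
) -> np.ndarray:
    """R = R_atom + alpha * (R_char + R_bpe) + beta * R_fp, elementwise."""
    shapes = {r_atom.shape, r_char.shape, r_bpe.shape, r_fp.shape}
    if len(shapes) != 1:
        raise ValueError(f"representation shapes differ: {shapes}")
    return r_atom + alpha * (r_char + r_bpe) + beta * r_fp


def _decode_batch(r: np.ndarray, params: Mapping[str, np.ndarray]) -> np.ndarray:
    return r @ params["dec_W"] + params["dec_b"][0]  # logits


def forward(
    features: Mapping[str, np.ndarray],
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    return_logits: bool = False,
    return_representation: bool = False,
):
    """Batched forward pass.

    *features* maps each view name to an (B, L_view) int id array and "fp"
    to the (B, 2215) fingerprint matrix. Returns probabilities in (0, 1).
    """
    reps = {view: _encode_seq_batch(features[view], params, view) for view in VIEWS}
    r_fp = _encode_fp_batch(features["fp"], params)
    r = fuse(reps["atom"], reps["char"], reps["bpe"], r_fp, config.alpha, config.beta)
    logits = _decode_batch(r, params)
    if return_representation:
        return r
    return logits if return_logits else nn.sigmoid(logits)


def forward_backward(
    features: Mapping[str, np.ndarray],
    labels: np.ndarray,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean BCE loss and gradients for every parameter on one minibatch."""
    cache: dict = {}
    reps = {view: _encode_seq_batch(features[view], params, view, cache) for view in VIEWS}
    r_fp = _encode_fp_batch(features["fp"], params, cache)
    r = fuse(reps["atom"], reps["char"], reps["bpe"], r_fp, config.alpha, config.beta)
    logits = _decode_batch(r, params)
    loss, dlogits = nn.bce_with_logits(logits, labels)

    grads: dict[str, np.ndarray] = {}
    grads["dec_W"] = r.T @ dlogits
    grads["dec_b"] = np.array([dlogits.sum()])
    dr = np.outer(dlogits, params["dec_W"])  # (B, R)

    # fingerprint branch
    dr_fp = config.beta * dr
    grads["fp_W2"] = cache["fp_a1"].T @ dr_fp
    grads["fp_b2"] = dr_fp.sum(axis=0)
    da1 = dr_fp @ params["fp_W2"].T
    dz1 = da1 * nn.swish_grad(cache["fp_z1"])
    grads["fp_W1"] = cache["fp_in"].T @ dz1
    grads["fp_b1"] = dz1.sum(axis=0)

    # sequence branches
    branch_scale = {"atom": 1.0, "char": config.alpha, "bpe": config.alpha}
    for view in VIEWS:
        dpooled = branch_scale[view] * dr  # (B, R)
        z2 = cache[f"{view}_z2"]
        B, L, R = z2.shape
        dh = np.zeros((B, L, R))
        bidx = np.arange(B)[:, None]
        ridx = np.arange(R)[None, :]
        dh[bidx, cache[f"{view}_argmax"], ridx] = dpooled
        dz2 = dh * nn.softplus_grad(z2)
        da1, dw2, db2 = nn.conv1d_same_backward(
            cache[f"{view}_a1"], params[f"conv2_{view}_W"], dz2
        )
        grads[f"conv2_{view}_W"] = dw2
        grads[f"conv2_{view}_b"] = db2
        dz1 = da1 * cache[f"{view}_mask"][:, :, None] * nn.softplus_grad(cache[f"{view}_z1"])
        dx, dw1, db1 = nn.conv1d_same_backward(
            cache[f"{view}_x"], params[f"conv1_{view}_W"], dz1
        )
        grads[f"conv1_{view}_W"] = dw1
        grads[f"conv1_{view}_b"] = db1
        demb = np.zeros_like(params[f"emb_{view}"])
        np.add.at(demb, cache[f"{view}_ids"], dx)
        demb[PAD_ID] = 0.0  # pad embedding stays pinned at zero
        grads[f"emb_{view}"] = demb
    return loss, grads


# ---------------------------------------------------------------------------
# single-sample convenience API
# ---------------------------------------------------------------------------


def encode_fingerprint(combined: np.ndarray, params: Mapping[str, np.ndarray]) -> np.ndarray:
    """R_fp for one molecule's combined fingerprint vector."""
    if combined.ndim != 1:
        raise ValueError("expected a single fingerprint vector")
    return _encode_fp_batch(combined[None, :], params)[0]


def encode_sequence(
    ids: np.ndarray, params: Mapping[str, np.ndarray], view: str
) -> np.ndarray:
    """R_view for one encoded token-id sequence."""
    ids = np.asarray(ids, dtype=np.int64)
    if ids.ndim != 1:
        raise ValueError("expected a single id sequence")
    return _encode_seq_batch(ids[None, :], params, view)[0]


def decode(r: np.ndarray, params: Mapping[str, np.ndarray]) -> float:
    """Probability in (0, 1) from one fused representation."""
    return float(nn.sigmoid(_decode_batch(np.asarray(r)[None, :], params)[0]))


# ---------------------------------------------------------------------------
# checkpoint persistence
# ---------------------------------------------------------------------------


def save_checkpoint(
    path: str | Path,
    params: Mapping[str, np.ndarray],
    config: ModelConfig,
    epoch: int | None = None,
    val_auprc: float | None = None,
) -> None:
    """Serialize a named-parameter map + config + metadata; round-trips bit-exactly."""
    meta = {"config": config.to_dict(), "epoch": epoch, "val_auprc": val_auprc}
    np.savez(path, __meta__=np.array(json.dumps(meta)), **params)


def load_checkpoint(path: str | Path):
    """Returns (params, config, epoch, val_auprc)."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        params = {k: data[k].copy() for k in data.files if k != "__meta__"}
    config = ModelConfig.from_dict(meta["config"])
    return params, config, meta.get("epoch"), meta.get("val_auprc")
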