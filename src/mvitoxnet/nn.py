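"""Minimal NumPy neural-network primitives: activations, 1-D convolution,
binary cross-entropy, and Adam.

Everything here operates on float64 arrays and provides explicit backward
passes; the gradients are checked against finite differences in the test
suite. Shapes follow the (batch, length, channels) convention.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as sigmoid

__all__ = [
    "sigmoid",
    "swish",
    "swish_grad",
    "softplus",
    "softplus_grad",
    "conv1d_same",
    "conv1d_same_backward",
    "bce_with_logits",
    "AdamOptimizer",
]


def swish(x: np.ndarray) -> np.ndarray:
    """Swish(x) = x * sigmoid(x)."""
    return x * sigmoid(x)


def swish_grad(x: np.ndarray) -> np.ndarray:
    s = sigmoid(x)
    return s * (1.0 + x * (1.0 - s))


def softplus(x: np.ndarray) -> np.ndarray:
    """Softplus(x) = log(1 + e^x), overflow-safe for large |x|."""
    return np.logaddexp(0.0, x)


def softplus_grad(x: np.ndarray) -> np.ndarray:
    return sigmoid(x)


def _patches(x_padded: np.ndarray, k: int) -> np.ndarray:
    # (B, L_out, C_in, k) sliding windows along the length axis
    return np.lib.stride_tricks.sliding_window_view(x_padded, k, axis=1)


def conv1d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """1-D convolution with zero 'same' padding.

    x: (B, L, C_in); w: (C_out, C_in, k) with k odd; b: (C_out,).
    Returns (B, L, C_out). Zero end-padding is equivalent to extending the
    sequence with pad tokens as long as the pad embedding row is held at
    zero, which is what makes masked pooling pad-extension invariant.
    """
    cout, cin, k = w.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    p = _patches(xp, k)  # (B, L, C_in, k)
    return np.tensordot(p, w, axes=([2, 3], [1, 2])) + b


def conv1d_same_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of conv1d_same: returns (dx, dw, db)."""
    cout, cin, k = w.shape
    pad = k // 2
    B, L, _ = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    p = _patches(xp, k)  # (B, L, C_in, k)
    dw = np.tensordot(dy, p, axes=([0, 1], [0, 1]))  # (C_out, C_in, k)
    db = dy.sum(axis=(0, 1))
    dxp = np.zeros_like(xp)
    for t in range(k):
        # y[:, i] consumed xp[:, i + t]
        dxp[:, t : t + L, :] += dy @ w[:, :, t]
    return dxp[:, pad : pad + L, :], dw, db


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from raw logits; returns (loss, dlogits)."""
    loss = float(np.mean(softplus(logits) - labels * logits))
    dlogits = (sigmoid(logits) - labels) / logits.shape[0]
    return loss, dlogits


class AdamOptimizer:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(
        self,
        param_names: list[str],
        learning_rate: float = 1e-5,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {name: None for name in param_names}
        self.v: dict[str, np.ndarray] = {name: None for name in param_names}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            if self.m[name] is None:
                self.m[name] = np.zeros_like(params[name])
                self.v[name] = np.zeros_like(params[name])
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
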