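"""Autograd-backed neural-network primitives.

Every layer is a pure function of ``(params, inputs)`` built from
``autograd.numpy`` operations, so the whole computation graph — including a
loss term that itself contains an input gradient — stays differentiable.
That property is what allows the second propagation step (parameter updates
through a saliency term) without a dedicated deep-learning framework.

Parameters are plain lists of ``numpy`` arrays; autograd differentiates
through list containers natively.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

# ---------------------------------------------------------------------------
# initialisation


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


# ---------------------------------------------------------------------------
# layers


def conv1d(x, weight, bias, stride: int = 1, padding: int = 0):
    """1-D convolution via window gather + einsum.

    x: (B, C_in, L); weight: (C_out, C_in, k); bias: (C_out,).
    Returns (B, C_out, L_out) with L_out = (L + 2*padding - k)//stride + 1.
    """
    k = weight.shape[2]
    if padding:
        zeros = np.zeros((x.shape[0], x.shape[1], padding))
        x = anp.concatenate([zeros, x, zeros], axis=2)
    length = x.shape[2]
    n_out = (length - k) // stride + 1
    # (L_out, k) gather index, a constant wrt the graph
    idx = (np.arange(n_out)[:, None] * stride) + np.arange(k)[None, :]
    windows = x[:, :, idx]  # (B, C_in, L_out, k)
    out = anp.einsum("bilk,oik->bol", windows, weight)
    return out + bias[None, :, None]


def relu(x):
    return anp.maximum(x, 0.0)


def dense(x, weight, bias):
    """x: (B, d_in); weight: (d_in, d_out)."""
    return anp.dot(x, weight) + bias


def max_pool_plane(x, pool_channels: int, pool_positions: int):
    """Max pooling over the (channel x position) plane of a conv stack.

    x: (B, C, L). Trailing remainders are cropped, as in floor-mode pooling.
    """
    b = x.shape[0]
    c = (x.shape[1] // pool_channels) * pool_channels
    length = (x.shape[2] // pool_positions) * pool_positions
    x = x[:, :c, :length]
    x = anp.reshape(
        x, (b, c // pool_channels, pool_channels, length // pool_positions, pool_positions)
    )
    return anp.max(anp.max(x, axis=4), axis=2)


def global_avg_pool(x):
    """x: (B, C, L) -> (B, C)."""
    return anp.mean(x, axis=2)


def flatten(x):
    return anp.reshape(x, (x.shape[0], -1))


def interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Linear-interpolation resize operator: (n_out, n_in) constant matrix.

    ``m_out = M @ m_in`` linearly resamples a length-``n_in`` profile to
    length ``n_out`` (endpoints aligned).
    """
    mat = np.zeros((n_out, n_in))
    if n_in == 1:
        mat[:, 0] = 1.0
        return mat
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    lo = np.minimum(lo, n_in - 2)
    frac = pos - lo
    mat[np.arange(n_out), lo] = 1.0 - frac
    mat[np.arange(n_out), lo + 1] = frac
    return mat


def log_softmax(logits):
    m = anp.max(logits, axis=1, keepdims=True)
    shifted = logits - m
    return shifted - anp.log(anp.sum(anp.exp(shifted), axis=1, keepdims=True))


def cross_entropy(logits, labels, reduction: str = "mean"):
    """Multiclass cross-entropy from raw logits.

    labels: int array (B,). reduction: 'mean' | 'sum' | 'none'.
    """
    lsm = log_softmax(logits)
    nll = -lsm[np.arange(len(labels)), labels]
    if reduction == "mean":
        return anp.mean(nll)
    if reduction == "sum":
        return anp.sum(nll)
    return nll


# ---------------------------------------------------------------------------
# optimiser


class Adam:
    """Adam over a list of parameter arrays. Stateful, deterministic."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> list[np.ndarray]:
        self.t += 1
        out = []
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out
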