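"""Shared neural-network primitives on numpy + autograd.

All model parameters live in nested dicts of plain ``numpy`` arrays; the
forward functions are written against :mod:`autograd.numpy` so that
reverse-mode gradients of any scalar loss are available via
:func:`autograd.grad`.  Training uses the hand-rolled :class:`Adam`
optimizer below operating on the flattened parameter vector.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.misc import flatten
from autograd.scipy.special import erf

__all__ = [
    "ValidationError",
    "gelu",
    "softmax",
    "log_softmax",
    "layer_norm",
    "scaled_dot_attention",
    "multi_head_attention",
    "dense",
    "init_dense",
    "init_layer_norm",
    "count_params",
    "Adam",
    "unbox",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


def unbox(a):
    """Strip autograd tracing boxes, returning the underlying ndarray.

    Used where a value feeds an integer index computation: indices are
    piecewise constant in the inputs, so they carry no gradient and may be
    computed on concrete values.
    """
    while hasattr(a, "_value"):
        a = a._value
    return a


def gelu(x):
    """Gaussian error linear unit, exact erf form."""
    return 0.5 * x * (1.0 + erf(x / anp.sqrt(2.0)))


def softmax(x, axis=-1):
    """Numerically stable softmax along ``axis``."""
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def log_softmax(x, axis=-1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    return z - anp.log(anp.sum(anp.exp(z), axis=axis, keepdims=True))


def layer_norm(x, gain, bias, eps=1e-6):
    """Layer normalization over the last axis."""
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return gain * (x - mu) / anp.sqrt(var + eps) + bias


def dense(x, params):
    return anp.matmul(x, params["W"]) + params["b"]


def init_dense(rng, d_in, d_out, scale=None):
    """Gaussian init with 1/sqrt(d_in) scale (truncated-normal-free variant)."""
    if scale is None:
        scale = 1.0 / np.sqrt(d_in)
    return {"W": rng.normal(0.0, scale, size=(d_in, d_out)), "b": np.zeros(d_out)}


def init_layer_norm(d):
    return {"gain": np.ones(d), "bias": np.zeros(d)}


def scaled_dot_attention(q, k, v, bias=None, mask=None):
    """softmax(q kᵀ / sqrt(d_k) [+ bias] [+ mask]) v.

    ``q``: (..., n_q, d_k), ``k``: (..., n_k, d_k), ``v``: (..., n_k, d_v).
    ``bias`` broadcasts against the (..., n_q, n_k) score array (the learned
    relative-position bias of windowed attention); ``mask`` is an additive
    array of 0 / -inf-like large negatives used for shifted-window masking.
    """
    d_k = q.shape[-1]
    if k.shape[-1] != d_k:
        raise ValidationError(
            f"query dim {d_k} != key dim {k.shape[-1]}")
    if v.shape[-2] != k.shape[-2]:
        raise ValidationError(
            f"value rows {v.shape[-2]} != key rows {k.shape[-2]}")
    scores = anp.matmul(q, anp.swapaxes(k, -1, -2)) / anp.sqrt(float(d_k))
    if bias is not None:
        scores = scores + bias
    if mask is not None:
        scores = scores + mask
    return anp.matmul(softmax(scores, axis=-1), v)


def attention_weights(q, k, bias=None, mask=None):
    """The post-softmax attention matrix, for instrumentation/tests."""
    d_k = q.shape[-1]
    scores = anp.matmul(q, anp.swapaxes(k, -1, -2)) / anp.sqrt(float(d_k))
    if bias is not None:
        scores = scores + bias
    if mask is not None:
        scores = scores + mask
    return softmax(scores, axis=-1)


def init_multi_head_attention(rng, d_model, num_heads):
    if d_model % num_heads != 0:
        raise ValidationError(
            f"model dim {d_model} not divisible by {num_heads} heads")
    return {
        "qkv": init_dense(rng, d_model, 3 * d_model),
        "proj": init_dense(rng, d_model, d_model),
    }


def multi_head_attention(x, params, num_heads, bias=None, mask=None):
    """Multi-head self-attention over token sequences.

    ``x``: (B, N, D).  ``bias``/``mask`` broadcast against (B, heads, N, N).
    """
    B, N, D = x.shape
    dh = D // num_heads
    qkv = dense(x, params["qkv"])  # (B, N, 3D)
    qkv = anp.reshape(qkv, (B, N, 3, num_heads, dh))
    qkv = anp.transpose(qkv, (2, 0, 3, 1, 4))  # (3, B, h, N, dh)
    q, k, v = qkv[0], qkv[1], qkv[2]
    out = scaled_dot_attention(q, k, v, bias=bias, mask=mask)  # (B, h, N, dh)
    out = anp.reshape(anp.transpose(out, (0, 2, 1, 3)), (B, N, D))
    return dense(out, params["proj"])


def init_mlp(rng, d_model, d_hidden):
    return {
        "fc1": init_dense(rng, d_model, d_hidden),
        "fc2": init_dense(rng, d_hidden, d_model),
    }


def mlp(x, params):
    """Two-layer feed-forward block with GELU."""
    return dense(gelu(dense(x, params["fc1"])), params["fc2"])


def count_params(params) -> int:
    """Total number of scalars in a nested parameter container."""
    flat, _ = flatten(params)
    return int(flat.size)


def l2_penalty(params, exclude_substrings=("gain", "bias", "b", "table")):
    """Sum of squares of weight matrices, skipping biases/norm gains.

    Walks the nested dict; a leaf is penalised unless its key is a bias or
    normalization parameter (1-D arrays are skipped, which covers biases,
    gains, and the class token is 2-D+ and intentionally penalised-free via
    its key).
    """
    total = 0.0

    def walk(node, key=""):
        nonlocal total
        if isinstance(node, dict):
            for k, v in node.items():
                walk(v, k)
        elif isinstance(node, (list, tuple)):
            for v in node:
                walk(v, key)
        else:
            if key in ("W", "E") and getattr(node, "ndim", 0) >= 2:
                total = total + anp.sum(node ** 2)

    walk(params)
    return total


class Adam:
    """Adam on the flattened parameter vector.

    Defaults follow the training recipe used throughout the package:
    learning rate 1e-4, (0.9, 0.999) moments.
    """

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        flat, self._unflatten = flatten(params)
        self.x = flat.astype(float).copy()
        self.m = np.zeros_like(self.x)
        self.v = np.zeros_like(self.x)
        self.t = 0
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps

    @property
    def params(self):
        return self._unflatten(self.x)

    def step(self, grads):
        g, _ = flatten(grads)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = self.b2 * self.v + (1 - self.b2) * g ** 2
        mhat = self.m / (1 - self.b1 ** self.t)
        vhat = self.v / (1 - self.b2 ** self.t)
        self.x = self.x - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return self.params
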