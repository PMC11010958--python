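"""ViTCol: a vision-transformer classifier of endoscopic pathological
findings, boosted by a spatial transformer front end.

Pipeline: spatial transform (affine localization of the lesion) ->
non-overlapping PxP patchify -> linear patch embedding with a learnable
class token and positional embeddings -> L pre-norm transformer encoder
blocks -> layer norm -> classification head (flatten, batch norm, dense,
softmax) reading only the class token.  Training minimizes multiclass
cross-entropy.

Presets mirror the standard ViT family: ``vitb_16`` (12 layers, hidden 768,
MLP 3072, 12 heads, 16x16 patches), ``vitb_32`` (same, 32x32 patches) and
``vitl_32`` (24 layers, hidden 1024, MLP 4096, 16 heads, 32x32 patches).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import autograd.numpy as anp
import numpy as np

from . import stn
from .nn import (ValidationError, dense, init_dense, init_layer_norm,
                 init_mlp, init_multi_head_attention, layer_norm, log_softmax,
                 mlp, multi_head_attention, scaled_dot_attention, softmax,
                 unbox)

attention = scaled_dot_attention


@dataclass(frozen=True)
class ViTConfig:
    """Architecture hyperparameters of the classifier."""

    image_size: int = 224
    patch_size: int = 16
    depth: int = 12
    hidden_size: int = 768
    mlp_size: int = 3072
    num_heads: int = 12
    num_classes: int = 3
    channels: int = 3
    dropout: float = 0.0
    use_stn: bool = True

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ValidationError(
                f"image size {self.image_size} not divisible by patch size "
                f"{self.patch_size}")
        if self.hidden_size % self.num_heads != 0:
            raise ValidationError(
                f"hidden size {self.hidden_size} not divisible by "
                f"{self.num_heads} heads")

    @property
    def num_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2


PRESETS = {
    "vitb_16": ViTConfig(patch_size=16, depth=12, hidden_size=768,
                         mlp_size=3072, num_heads=12),
    "vitb_32": ViTConfig(patch_size=32, depth=12, hidden_size=768,
                         mlp_size=3072, num_heads=12),
    "vitl_32": ViTConfig(patch_size=32, depth=24, hidden_size=1024,
                         mlp_size=4096, num_heads=16),
}


def preset(name: str, **overrides) -> ViTConfig:
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


def patchify(u, patch_size: int):
    """Split (B, H, W, C) images into row-major flattened PxP patches.

    Returns (B, N, P*P*C) with N = (H/P)(W/P); lossless (see unpatchify).
    """
    B, H, W, C = unbox(u).shape
    P = patch_size
    for name, dim in (("height", H), ("width", W)):
        if dim % P != 0:
            raise ValidationError(
                f"image {name} {dim} not divisible by patch size {P}")
    x = anp.reshape(u, (B, H // P, P, W // P, P, C))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))  # (B, h, w, P, P, C)
    return anp.reshape(x, (B, (H // P) * (W // P), P * P * C))


def unpatchify(patches, image_size: int, patch_size: int, channels: int = 3):
    """Inverse of :func:`patchify` for square images."""
    B = unbox(patches).shape[0]
    P, C = patch_size, channels
    g = image_size // P
    x = anp.reshape(patches, (B, g, g, P, P, C))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    return anp.reshape(x, (B, image_size, image_size, C))


def embed(patches, E, class_token, pos_emb):
    """Project patches and prepend the class token; add positional embeddings.

    token_0 = class_token + pos_emb_0; token_i = E . patch_i + pos_emb_i.
    ``E``: (P*P*C, D); ``class_token``: (D,); ``pos_emb``: (N+1, D).
    """
    pshape = unbox(patches).shape
    B, N = pshape[0], pshape[1]
    if unbox(E).shape[0] != pshape[2]:
        raise ValidationError(
            f"embedding matrix expects patch length {unbox(E).shape[0]}, "
            f"got {pshape[2]}")
    if unbox(pos_emb).shape[0] != N + 1:
        raise ValidationError(
            f"positional embedding length {unbox(pos_emb).shape[0]} != N+1 = {N + 1}")
    proj = anp.matmul(patches, E)  # (B, N, D)
    cls = anp.broadcast_to(anp.reshape(class_token, (1, 1, -1)),
                           (B, 1, unbox(class_token).shape[-1]))
    tokens = anp.concatenate([cls, proj], axis=1)
    return tokens + pos_emb[None]


def init_encoder_block(rng, cfg: ViTConfig):
    p = {
        "ln1": init_layer_norm(cfg.hidden_size),
        "attn": init_multi_head_attention(rng, cfg.hidden_size, cfg.num_heads),
        "ln2": init_layer_norm(cfg.hidden_size),
        "mlp": init_mlp(rng, cfg.hidden_size, cfg.mlp_size),
    }
    # identity-at-init: zero residual-branch outputs so a fresh encoder is
    # the identity map over tokens (stable early training)
    p["attn"]["proj"]["W"] *= 0.0
    p["mlp"]["fc2"]["W"] *= 0.0
    return p


def encoder_block(tokens, params, num_heads: int, attn_sink=None):
    """Pre-norm transformer block: x + MSA(LN(x)), then + MLP(LN(.)).

    ``attn_sink``: optional list collecting the per-layer post-softmax
    attention arrays for instrumentation.
    """
    h = layer_norm(tokens, params["ln1"]["gain"], params["ln1"]["bias"])
    if attn_sink is not None:
        from .nn import attention_weights
        B, N, D = unbox(h).shape
        dh = D // num_heads
        qkv = dense(h, params["attn"]["qkv"])
        qkv = anp.reshape(qkv, (B, N, 3, num_heads, dh))
        qkv = anp.transpose(qkv, (2, 0, 3, 1, 4))
        attn_sink.append(unbox(attention_weights(qkv[0], qkv[1])))
    tokens = tokens + multi_head_attention(h, params["attn"], num_heads)
    h2 = layer_norm(tokens, params["ln2"]["gain"], params["ln2"]["bias"])
    return tokens + mlp(h2, params["mlp"])


def batch_norm(x, params, state=None, eps=1e-5):
    """Batch normalization over the batch axis of (B, D) features.

    With ``state`` (running mean/var) given, normalizes with it (inference);
    otherwise uses the batch statistics (training / stateless use).
    """
    if state is not None:
        mu, var = state["mean"], state["var"]
    else:
        mu = anp.mean(x, axis=0)
        var = anp.var(x, axis=0)
    return params["gain"] * (x - mu) / anp.sqrt(var + eps) + params["bias"]


def mlp_head(cls_vec, params, bn_state=None, return_logits=False):
    """Classification head: flatten -> batch norm -> dense -> softmax.

    Consumes only the class-token vector; the encoder's other outputs are
    ignored by design.
    """
    x = anp.reshape(cls_vec, (unbox(cls_vec).shape[0], -1))
    x = batch_norm(x, params["bn"], state=bn_state)
    logits = dense(x, params["out"])
    if return_logits:
        return logits
    return softmax(logits, axis=-1)


def cross_entropy(logits, labels, num_classes=None, from_logits=True):
    """Mean multiclass cross-entropy, -log p(true class).

    Computed in log-sum-exp form when ``from_logits`` (numerically stable);
    ``labels`` are integer class indices.
    """
    labels = np.asarray(labels)
    C = unbox(logits).shape[-1]
    if num_classes is not None and num_classes != C:
        raise ValidationError(f"expected {num_classes} classes, got {C}")
    if labels.min() < 0 or labels.max() >= C:
        raise ValidationError(
            f"label out of range [0, {C}): {labels.min()}..{labels.max()}")
    if from_logits:
        logp = log_softmax(logits, axis=-1)
    else:
        logp = anp.log(anp.maximum(logits, 1e-300))
    n = labels.shape[0]
    return -anp.mean(logp[np.arange(n), labels])


def init_vitcol_params(cfg: ViTConfig, rng, emb_scale=0.02):
    """Initialize all weights.  Positional/class embeddings are Gaussian
    (sigma=0.02); the localization head starts at the identity transform."""
    D = cfg.hidden_size
    patch_len = cfg.patch_size ** 2 * cfg.channels
    params = {
        "embed": {
            "E": rng.normal(0.0, 1.0 / np.sqrt(patch_len),
                            size=(patch_len, D)),
            "class_token": rng.normal(0.0, emb_scale, size=D),
            "pos": rng.normal(0.0, emb_scale, size=(cfg.num_patches + 1, D)),
        },
        "blocks": [init_encoder_block(rng, cfg) for _ in range(cfg.depth)],
        "ln_final": init_layer_norm(D),
        "head": {
            "bn": {"gain": np.ones(D), "bias": np.zeros(D)},
            "out": init_dense(rng, D, cfg.num_classes),
        },
    }
    if cfg.use_stn:
        params["stn"] = stn.init_localization_params(rng, cfg.channels)
    return params


def encode(u, cfg: ViTConfig, params, theta_override=None, attn_sink=None):
    """Everything up to (and including) the final layer norm; returns tokens."""
    if cfg.use_stn or theta_override is not None:
        v = stn.spatial_transform(u, params.get("stn"),
                                  theta_override=theta_override)
    else:
        v = u
    patches = patchify(v, cfg.patch_size)
    tokens = embed(patches, params["embed"]["E"],
                   params["embed"]["class_token"], params["embed"]["pos"])
    for blk in params["blocks"]:
        tokens = encoder_block(tokens, blk, cfg.num_heads, attn_sink=attn_sink)
    return layer_norm(tokens, params["ln_final"]["gain"],
                      params["ln_final"]["bias"])


def vitcol_forward(u, cfg: ViTConfig, params, theta_override=None,
                   bn_state=None, return_logits=False, attn_sink=None):
    """Full classifier forward pass; returns per-image class probabilities
    (rows sum to 1) or logits."""
    tokens = encode(u, cfg, params, theta_override=theta_override,
                    attn_sink=attn_sink)
    return mlp_head(tokens[:, 0, :], params["head"], bn_state=bn_state,
                    return_logits=return_logits)
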