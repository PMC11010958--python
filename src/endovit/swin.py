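"""PUTS: polyp segmentation with a spatial-transformer front end and a
Swin-Unet encoder-decoder.

The network localizes the input with an affine spatial transformer, splits
the localized image into non-overlapping 4x4 patches, and processes the
token grid with a U-shaped hierarchy of Swin transformer blocks.  Blocks
come in pairs: the first restricts multi-head self-attention to
non-overlapping MxM windows (W-MSA), the second to windows shifted by
floor(M/2) with an attention mask that forbids attention between tokens
that were not spatially contiguous before the cyclic shift (SW-MSA):

    z_hat^l   = W-MSA(LN(z^{l-1})) + z^{l-1}
    z^l       = MLP(LN(z_hat^l)) + z_hat^l
    z_hat^l+1 = SW-MSA(LN(z^l)) + z^l
    z^l+1     = MLP(LN(z_hat^{l+1})) + z_hat^{l+1}

Window attention adds a learned relative-position bias B to the logits:
softmax(Q K^T / sqrt(d) + B) V, with one bias scalar per head per relative
offset (a (2M-1)^2-entry table).

Patch merging halves the resolution (concatenate each 2x2 neighbourhood,
linear 4d -> 2d); patch expanding is its learned inverse.  Skip connections
concatenate encoder features with decoder features at matching resolution,
followed by a linear projection back to the stage dimension.  A final 4x
expansion and a per-pixel linear classifier return a softmax probability
map at full input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

from . import stn
from .nn import (ValidationError, dense, init_dense, init_layer_norm,
                 init_mlp, init_multi_head_attention, layer_norm, log_softmax,
                 mlp, multi_head_attention, softmax, unbox)

MASK_NEG = -1e9


@dataclass(frozen=True)
class SwinConfig:
    """Architecture hyperparameters of the segmenter.

    ``depths`` lists the (even) number of Swin blocks at each resolution
    level of the encoder; the last entry is the bottleneck at the deepest
    resolution.  ``heads`` has one entry per level.
    """

    image_size: int = 224
    patch_size: int = 4
    embed_dim: int = 96
    depths: tuple = (2, 2, 2, 2)
    heads: tuple = (3, 6, 12, 24)
    window_size: int = 7
    num_classes: int = 2
    channels: int = 3
    use_stn: bool = True

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ValidationError("image size not divisible by patch size")
        if len(self.heads) != len(self.depths):
            raise ValidationError("need one head count per level")
        res = self.image_size // self.patch_size
        for i, d in enumerate(self.depths):
            if d % 2 != 0:
                raise ValidationError(
                    "depths must be even (blocks come in W-MSA/SW-MSA pairs)")
            r = res // (2 ** i)
            if r % self.window_size != 0:
                raise ValidationError(
                    f"level {i} resolution {r} not divisible by window "
                    f"{self.window_size}")
            dim = self.embed_dim * (2 ** i)
            if dim % self.heads[i] != 0:
                raise ValidationError(
                    f"level {i} dim {dim} not divisible by {self.heads[i]} heads")

    @property
    def num_levels(self) -> int:
        return len(self.depths)


# ---------------------------------------------------------------------------
# windows

def window_partition(fm, window_size: int):
    """(B, h, w, d) -> (B * h/M * w/M, M*M, d), windows in row-major order."""
    B, h, w, d = unbox(fm).shape
    M = window_size
    if h % M or w % M:
        raise ValidationError(
            f"feature map {h}x{w} not divisible by window size {M}")
    x = anp.reshape(fm, (B, h // M, M, w // M, M, d))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    return anp.reshape(x, (B * (h // M) * (w // M), M * M, d))


def window_reverse(windows, h: int, w: int, window_size: int):
    """Exact inverse of :func:`window_partition`."""
    M = window_size
    if h % M or w % M:
        raise ValidationError(
            f"target map {h}x{w} not divisible by window size {M}")
    nW = (h // M) * (w // M)
    n = unbox(windows).shape[0]
    if n % nW:
        raise ValidationError(
            f"{n} windows do not tile a {h}x{w} map with M={M}")
    B = n // nW
    d = unbox(windows).shape[-1]
    x = anp.reshape(windows, (B, h // M, w // M, M, M, d))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    return anp.reshape(x, (B, h, w, d))


# ---------------------------------------------------------------------------
# relative position bias

def relative_position_index(window_size: int):
    """Index map from each intra-window (query, key) pair to the entry of
    the (2M-1)^2 relative-offset table; depends only on the pair's offset."""
    M = window_size
    coords = np.stack(np.meshgrid(np.arange(M), np.arange(M),
                                  indexing="ij"), axis=0)  # (2, M, M)
    flat = coords.reshape(2, -1)  # (2, M^2)
    rel = flat[:, :, None] - flat[:, None, :]  # (2, M^2, M^2)
    rel = rel + (M - 1)
    return rel[0] * (2 * M - 1) + rel[1]  # (M^2, M^2) in [0, (2M-1)^2)


def relative_position_bias(table, window_size: int):
    """(heads, M^2, M^2) bias from the learned ((2M-1)^2, heads) table."""
    idx = relative_position_index(window_size)
    bias = table[idx]  # (M^2, M^2, heads)
    return anp.transpose(bias, (2, 0, 1))


# ---------------------------------------------------------------------------
# windowed attention

def w_msa(fm, params, window_size: int, num_heads: int, mask=None):
    """Window-based multi-head self-attention with relative-position bias.

    Attention is computed independently inside each MxM window; no
    information crosses window boundaries.  ``mask`` (nW, M^2, M^2), when
    given, is added to the logits per window position (SW-MSA masking).
    """
    B, h, w, d = unbox(fm).shape
    M = window_size
    windows = window_partition(fm, M)  # (B*nW, M^2, d)
    bias = relative_position_bias(params["bias_table"], M)[None]  # (1,h,M2,M2)
    addmask = None
    if mask is not None:
        nW = mask.shape[0]
        full = np.tile(mask, (B, 1, 1))  # (B*nW, M^2, M^2)
        addmask = full[:, None, :, :]  # broadcast over heads
    out = multi_head_attention(windows, params, num_heads,
                               bias=bias, mask=addmask)
    return window_reverse(out, h, w, M)


def cyclic_shift(fm, shift: int):
    """Roll the (B, h, w, d) map by ``shift`` (possibly negative) along both
    spatial axes; differentiable (slice + concatenate)."""
    _, h, w, _ = unbox(fm).shape
    sh, sw = shift % h, shift % w
    if sh:
        fm = anp.concatenate([fm[:, -sh:], fm[:, :-sh]], axis=1)
    if sw:
        fm = anp.concatenate([fm[:, :, -sw:], fm[:, :, :-sw]], axis=2)
    return fm


def sw_msa_mask(h: int, w: int, window_size: int):
    """Additive attention mask for shifted-window attention.

    Tokens are labelled by the contiguous region they came from before the
    cyclic shift; pairs from different regions get a large negative logit
    so their post-softmax weight is ~0.  Returns (nW, M^2, M^2).
    """
    M = window_size
    s = M // 2
    img = np.zeros((1, h, w, 1))
    cnt = 0
    for hs in (slice(0, -M), slice(-M, -s), slice(-s, None)):
        for ws in (slice(0, -M), slice(-M, -s), slice(-s, None)):
            img[:, hs, ws, :] = cnt
            cnt += 1
    win = unbox(window_partition(img, M))[:, :, 0]  # (nW, M^2)
    diff = win[:, :, None] - win[:, None, :]
    return np.where(diff != 0, MASK_NEG, 0.0)


def sw_msa(fm, params, window_size: int, num_heads: int):
    """Shifted-window attention: cyclic shift by floor(M/2), masked W-MSA,
    reverse shift."""
    B, h, w, d = unbox(fm).shape
    M = window_size
    s = M // 2
    shifted = cyclic_shift(fm, -s)
    mask = sw_msa_mask(h, w, M)
    out = w_msa(shifted, params, M, num_heads, mask=mask)
    return cyclic_shift(out, s)


# ---------------------------------------------------------------------------
# blocks

def init_swin_block(rng, dim: int, num_heads: int, window_size: int,
                    mlp_ratio: int = 4):
    M = window_size
    p = {
        "ln1": init_layer_norm(dim),
        "attn": init_multi_head_attention(rng, dim, num_heads),
        "ln2": init_layer_norm(dim),
        "mlp": init_mlp(rng, dim, mlp_ratio * dim),
    }
    p["attn"]["bias_table"] = rng.normal(
        0.0, 0.02, size=((2 * M - 1) ** 2, num_heads))
    # identity-at-init: zero the residual-branch output weights so a fresh
    # block is the identity map and optimization starts from stable features
    p["attn"]["proj"]["W"] *= 0.0
    p["mlp"]["fc2"]["W"] *= 0.0
    return p


def swin_block(fm, params, window_size: int, num_heads: int, shifted: bool):
    """One Swin block: (S)W-MSA with residual, then MLP with residual."""
    h1 = layer_norm(fm, params["ln1"]["gain"], params["ln1"]["bias"])
    if shifted:
        a = sw_msa(h1, params["attn"], window_size, num_heads)
    else:
        a = w_msa(h1, params["attn"], window_size, num_heads)
    fm = fm + a
    h2 = layer_norm(fm, params["ln2"]["gain"], params["ln2"]["bias"])
    return fm + mlp(h2, params["mlp"])


def swin_block_pair(fm, params_pair, window_size: int, num_heads: int):
    """The canonical W-MSA / SW-MSA block pair (the four-equation unit)."""
    fm = swin_block(fm, params_pair[0], window_size, num_heads, shifted=False)
    return swin_block(fm, params_pair[1], window_size, num_heads, shifted=True)


# ---------------------------------------------------------------------------
# merging / expanding

def init_patch_merging(rng, dim: int):
    return {"ln": init_layer_norm(4 * dim), "reduce": init_dense(rng, 4 * dim, 2 * dim)}


def patch_merging(fm, params):
    """Concatenate each 2x2 neighbourhood and project 4d -> 2d.

    (B, h, w, d) -> (B, h/2, w/2, 2d); h and w must be even.
    """
    B, h, w, d = unbox(fm).shape
    if h % 2 or w % 2:
        raise ValidationError(f"patch merging needs even h, w; got {h}x{w}")
    x0 = fm[:, 0::2, 0::2, :]
    x1 = fm[:, 1::2, 0::2, :]
    x2 = fm[:, 0::2, 1::2, :]
    x3 = fm[:, 1::2, 1::2, :]
    x = anp.concatenate([x0, x1, x2, x3], axis=-1)  # (B, h/2, w/2, 4d)
    x = layer_norm(x, params["ln"]["gain"], params["ln"]["bias"])
    return dense(x, params["reduce"])


def init_patch_expanding(rng, dim: int, factor: int):
    if factor == 2:
        out = 2 * dim  # rearranged to 2h x 2w x d/2
        ln_dim = dim // 2
    elif factor == 4:
        out = 16 * dim  # rearranged to 4h x 4w x d
        ln_dim = dim
    else:
        raise ValidationError("expansion factor must be 2 or 4")
    return {"proj": init_dense(rng, dim, out), "ln": init_layer_norm(ln_dim)}


def _pixel_shuffle(x, p: int):
    """(B, h, w, p*p*c) -> (B, p*h, p*w, c) rearrangement."""
    B, h, w, dd = unbox(x).shape
    c = dd // (p * p)
    x = anp.reshape(x, (B, h, w, p, p, c))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    return anp.reshape(x, (B, h * p, w * p, c))


def patch_expanding(fm, params, factor: int = 2):
    """Learned upsampling: linear projection then pixel-shuffle rearrangement.

    factor 2: (B, h, w, d) -> (B, 2h, 2w, d/2);
    factor 4: (B, h, w, d) -> (B, 4h, 4w, d) (the final expansion before the
    per-pixel classifier).
    """
    if factor not in (2, 4):
        raise ValidationError("expansion factor must be 2 or 4")
    x = dense(fm, params["proj"])
    x = _pixel_shuffle(x, factor)
    return layer_norm(x, params["ln"]["gain"], params["ln"]["bias"])


# ---------------------------------------------------------------------------
# full model

def init_puts_params(cfg: SwinConfig, rng):
    C0 = cfg.embed_dim
    M = cfg.window_size
    L = cfg.num_levels
    params = {
        "patch_embed": {
            "proj": init_dense(rng, cfg.patch_size ** 2 * cfg.channels, C0),
            "ln": init_layer_norm(C0),
        },
        "enc": [], "dec": [],
    }
    if cfg.use_stn:
        params["stn"] = stn.init_localization_params(rng, cfg.channels)
    # encoder levels 0..L-2, each followed by merging
    for i in range(L - 1):
        dim = C0 * 2 ** i
        params["enc"].append({
            "blocks": [init_swin_block(rng, dim, cfg.heads[i], M)
                       for _ in range(cfg.depths[i])],
            "merge": init_patch_merging(rng, dim),
        })
    # bottleneck at level L-1
    dim = C0 * 2 ** (L - 1)
    params["bottleneck"] = [init_swin_block(rng, dim, cfg.heads[-1], M)
                            for _ in range(cfg.depths[-1])]
    # decoder levels L-2..0
    for i in range(L - 2, -1, -1):
        dim = C0 * 2 ** i
        params["dec"].append({
            "expand": init_patch_expanding(rng, 2 * dim, 2),
            "skip": init_dense(rng, 2 * dim, dim),
            "blocks": [init_swin_block(rng, dim, cfg.heads[i], M)
                       for _ in range(cfg.depths[i])],
        })
    params["final_expand"] = init_patch_expanding(rng, C0, 4)
    params["head"] = init_dense(rng, C0, cfg.num_classes)
    # start from uniform per-pixel predictions rather than random logits
    params["head"]["W"] *= 0.0
    return params


def patch_embed(v, cfg: SwinConfig, params):
    """Non-overlapping 4x4 patch split + linear embedding -> (B, h, w, C)."""
    B, H, W, C = unbox(v).shape
    P = cfg.patch_size
    x = anp.reshape(v, (B, H // P, P, W // P, P, C))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    x = anp.reshape(x, (B, H // P, W // P, P * P * C))
    x = dense(x, params["proj"])
    return layer_norm(x, params["ln"]["gain"], params["ln"]["bias"])


def _run_blocks(fm, blocks, M, heads):
    for i in range(0, len(blocks), 2):
        fm = swin_block_pair(fm, blocks[i:i + 2], M, heads)
    return fm


def puts_logits(u, cfg: SwinConfig, params, theta_override=None):
    """Per-pixel class logits at full input resolution (B, H, W, K)."""
    stn.check_image_batch(u)
    if cfg.use_stn or theta_override is not None:
        v = stn.spatial_transform(u, params.get("stn"),
                                  theta_override=theta_override)
    else:
        v = u
    M = cfg.window_size
    x = patch_embed(v, cfg, params["patch_embed"])
    skips = []
    for i, stage in enumerate(params["enc"]):
        x = _run_blocks(x, stage["blocks"], M, cfg.heads[i])
        skips.append(x)
        x = patch_merging(x, stage["merge"])
    x = _run_blocks(x, params["bottleneck"], M, cfg.heads[-1])
    for j, stage in enumerate(params["dec"]):
        level = cfg.num_levels - 2 - j
        x = patch_expanding(x, stage["expand"], factor=2)
        x = anp.concatenate([x, skips[level]], axis=-1)
        x = dense(x, stage["skip"])
        x = _run_blocks(x, stage["blocks"], M, cfg.heads[level])
    x = patch_expanding(x, params["final_expand"], factor=4)
    return dense(x, params["head"])


def puts_forward(u, cfg: SwinConfig, params, theta_override=None):
    """Soft segmentation mask: per-pixel class probabilities summing to 1."""
    return softmax(puts_logits(u, cfg, params, theta_override=theta_override),
                   axis=-1)


def check_binary_mask(mask):
    m = unbox(mask)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValidationError(
            f"mask is not binary; found values {vals[:10]}")


def seg_loss(pred_soft, truth):
    """Pixel-wise categorical cross-entropy between a soft prediction
    (B, H, W, K) and an integer label mask (B, H, W), averaged over pixels."""
    t = np.asarray(unbox(truth)).astype(int)
    pshape = unbox(pred_soft).shape
    if pshape[:3] != t.shape:
        raise ValidationError(
            f"prediction {pshape[:3]} and truth {t.shape} shapes differ")
    onehot = np.eye(pshape[-1])[t]  # (B, H, W, K)
    logp = anp.log(anp.maximum(pred_soft, 1e-300))
    return -anp.mean(anp.sum(onehot * logp, axis=-1))


def seg_loss_from_logits(logits, truth):
    """Stable log-sum-exp form of the pixel-wise cross-entropy (training)."""
    t = np.asarray(unbox(truth)).astype(int)
    K = unbox(logits).shape[-1]
    onehot = np.eye(K)[t]
    logp = log_softmax(logits, axis=-1)
    return -anp.mean(anp.sum(onehot * logp, axis=-1))


def hard_mask(pred_soft):
    """Argmax decision (equivalently p >= 0.5 for two classes)."""
    return np.argmax(unbox(pred_soft), axis=-1).astype(np.uint8)
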