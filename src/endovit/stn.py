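"""Spatial transformer module: affine localization, grid generator, sampler.

A spatial transformer predicts, per image, a 2x3 affine matrix theta mapping
normalized *target* (output) coordinates to *source* (input) coordinates,

    [x_s, y_s]^T = A_theta [x_t, y_t, 1]^T,

builds the sampling grid over the regular output raster, and resamples the
input with differentiable bilinear interpolation.  The whole module is
differentiable in both the image and the localization weights, so the
transform is learned end-to-end from the downstream task loss alone
(weakly supervised localization).

Coordinate convention (used consistently by grid generator and sampler):
align-corners style, (-1, -1) is the *center* of the top-left pixel and
(+1, +1) the center of the bottom-right pixel.  Source coordinates outside
[-1, 1] sample zero padding.

The localization network itself is deliberately small: two 2x2/stride-2
convolution + GELU blocks, global average pooling, one hidden dense layer,
and a final dense layer producing the six affine entries.  The final layer
is zero-initialized with its bias set to the identity transform, so a fresh
spatial transformer is exactly the identity map.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from .nn import ValidationError, dense, gelu, init_dense, unbox

IDENTITY_THETA = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


def check_image_batch(u):
    """Validate the (batch, H, W, C) image contract; returns the shape."""
    u_c = unbox(u)
    if getattr(u_c, "ndim", 0) != 4:
        raise ValidationError(f"expected 4-axis (B,H,W,C) array, got ndim={getattr(u_c,'ndim',None)}")
    B, H, W, C = u_c.shape
    if H < 8 or W < 8:
        raise ValidationError(f"image too small: H={H}, W={W} (need >= 8)")
    if C not in (1, 3):
        raise ValidationError(f"channels must be 1 or 3, got {C}")
    if not np.all(np.isfinite(u_c)):
        raise ValidationError("image batch contains non-finite pixels")
    return B, H, W, C


def _space_to_depth(x, k):
    B, H, W, C = x.shape
    x = anp.reshape(x, (B, H // k, k, W // k, k, C))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    return anp.reshape(x, (B, H // k, W // k, k * k * C))


def init_localization_params(rng, in_channels=3, conv_dims=(16, 32), hidden=32):
    """Localization weights; final layer zero with identity bias."""
    c1, c2 = conv_dims
    params = {
        "conv1": init_dense(rng, 4 * in_channels, c1),
        "conv2": init_dense(rng, 4 * c1, c2),
        "fc1": init_dense(rng, c2, hidden),
        "fc2": {"W": np.zeros((hidden, 6)),
                "b": np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])},
    }
    return params


def localization_net(u, params):
    """Predict per-image affine parameters theta, shape (B, 2, 3).

    Freshly initialized weights yield the identity matrix for every input
    (identity-initialization contract), keeping early training stable.
    """
    B, H, W, C = check_image_batch(u)
    # crop to a multiple of 4 so the two stride-2 blocks divide evenly
    H4, W4 = (H // 4) * 4, (W // 4) * 4
    x = u[:, :H4, :W4, :]
    x = gelu(dense(_space_to_depth(x, 2), params["conv1"]))
    x = gelu(dense(_space_to_depth(x, 2), params["conv2"]))
    x = anp.mean(x, axis=(1, 2))  # global average pool -> (B, c2)
    x = gelu(dense(x, params["fc1"]))
    theta = dense(x, params["fc2"])
    return anp.reshape(theta, (B, 2, 3))


def generate_grid(theta, out_height, out_width):
    """Affine sampling grid over the regular output raster.

    For each target pixel with normalized coordinates (x_t, y_t):
        x_s = t11 x_t + t12 y_t + t13
        y_s = t21 x_t + t22 y_t + t23
    Returns (B, out_height, out_width, 2) with last axis (x_s, y_s).
    """
    if out_height < 1 or out_width < 1:
        raise ValidationError("output size must be >= 1")
    theta_c = unbox(theta)
    if theta_c.ndim != 3 or theta_c.shape[1:] != (2, 3):
        raise ValidationError(f"theta must be (B,2,3), got {theta_c.shape}")
    B = theta_c.shape[0]
    xs = np.linspace(-1.0, 1.0, out_width) if out_width > 1 else np.zeros(1)
    ys = np.linspace(-1.0, 1.0, out_height) if out_height > 1 else np.zeros(1)
    xt, yt = np.meshgrid(xs, ys)  # (H, W)
    ones = np.ones_like(xt)
    tgt = np.stack([xt, yt, ones], axis=-1)  # (H, W, 3)
    # (B,2,3) @ (H*W,3)^T  -> einsum over the homogeneous coordinate
    grid = anp.einsum("bij,hwj->bhwi", theta, tgt)  # (B, H, W, 2) = (x_s, y_s)
    return grid


def regular_grid(batch, out_height, out_width):
    """The identity sampling grid (what generate_grid gives for identity theta)."""
    theta = np.repeat(IDENTITY_THETA[None], batch, axis=0)
    return generate_grid(theta, out_height, out_width)


def bilinear_sample(u, grid):
    """Differentiable bilinear resampling of ``u`` at ``grid`` source coords.

    Each output pixel interpolates the four nearest input pixels around its
    source coordinate; samples outside the image contribute zero (zero
    padding).  Differentiable w.r.t. both ``u`` and ``grid``.
    """
    B, H, W, C = check_image_batch(u)
    grid_c = unbox(grid)
    if grid_c.shape[0] != B:
        raise ValidationError(
            f"grid batch {grid_c.shape[0]} != image batch {B}")
    gx, gy = grid[..., 0], grid[..., 1]
    # map normalized [-1,1] to pixel index space (align-corners)
    fx = (gx + 1.0) * 0.5 * (W - 1)
    fy = (gy + 1.0) * 0.5 * (H - 1)
    fx_c, fy_c = unbox(fx), unbox(fy)
    x0 = np.floor(fx_c).astype(int)
    y0 = np.floor(fy_c).astype(int)
    x1, y1 = x0 + 1, y0 + 1
    wx = fx - x0  # traced: gradients w.r.t. grid flow through the weights
    wy = fy - y0
    bidx = np.arange(B)[:, None, None]

    def corner(yi, xi):
        valid = ((xi >= 0) & (xi < W) & (yi >= 0) & (yi < H)).astype(float)
        xc = np.clip(xi, 0, W - 1)
        yc = np.clip(yi, 0, H - 1)
        return u[bidx, yc, xc, :] * valid[..., None]

    out = (corner(y0, x0) * ((1 - wx) * (1 - wy))[..., None]
           + corner(y0, x1) * (wx * (1 - wy))[..., None]
           + corner(y1, x0) * ((1 - wx) * wy)[..., None]
           + corner(y1, x1) * (wx * wy)[..., None])
    return out


def spatial_transform(u, params, theta_override=None,
                      out_height=None, out_width=None):
    """Full spatial transformer: localize -> grid -> sample.

    Output spatial size defaults to the input size so downstream patch
    counts are unchanged.  ``theta_override`` replaces the predicted theta
    (a (2,3) matrix or a (B,2,3) batch), used for ablations and tests.
    """
    B, H, W, C = check_image_batch(u)
    if theta_override is not None:
        theta = theta_override
        if unbox(theta).ndim == 2:
            theta = anp.repeat(anp.reshape(theta, (1, 2, 3)), B, axis=0)
    else:
        theta = localization_net(u, params)
    out_height = H if out_height is None else out_height
    out_width = W if out_width is None else out_width
    grid = generate_grid(theta, out_height, out_width)
    return bilinear_sample(u, grid)
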