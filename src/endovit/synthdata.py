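"""Seeded synthetic endoscopy-like fixtures and the augmentation pipeline.

Real gastrointestinal endoscopy frames show lesions (esophagitis streaking,
polyp domes, the granular friability of ulcerative colitis) on a smooth,
reddish mucosal background.  The generator emulates the two dataset layouts
the models consume without any photorealism claim:

* classification — three visually separable lesion textures on a
  mucosa-like low-frequency background, lesion placed uniformly at random
  so the spatial transformer has something to localize:
  class 0 "esophagitis-like": bright radial streaks;
  class 1 "polyp-like": one smooth bright ellipsoid with a specular
  highlight; class 2 "colitis-like": a dense dark speckle field.
* segmentation — 1-3 bright irregular elliptical blobs (sinusoidally
  perturbed radius) with the exact rasterized interior as the ground-truth
  binary mask.

Identical spec + seed gives a byte-identical dataset.  The augmentation
pipeline applies a single random affine draw — rotation up to +/-40 deg,
independent horizontal/vertical flips (probability 0.2 each), width/height
shifts up to +/-0.2 of the dimension, shear up to 0.1 and zoom up to
+/-0.1 — identically to image and mask (mask: nearest neighbour +
re-binarization).  Augmentation is an online training-time operation only.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .nn import ValidationError

CLASS_NAMES = ("esophagitis", "polyps", "ulcerative-colitis")

MUCOSA_RGB = np.array([0.72, 0.42, 0.38])


@dataclass(frozen=True)
class SynthSpec:
    """Full description of one synthetic dataset; determinism contract:
    identical spec + seed -> byte-identical arrays."""

    task: str = "classification"
    image_size: int = 64
    n_per_class: int = 100          # classification
    n_images: int = 200             # segmentation
    blob_count: tuple = (1, 3)      # segmentation blobs per image
    radius_range: tuple = (0.10, 0.22)  # blob radius, fraction of image
    irregularity: float = 0.25      # sinusoidal radius perturbation amplitude
    background_sigma: float = 0.12  # low-frequency background scale (x size)
    noise_level: float = 0.02       # additive pixel noise sigma
    seed: int = 0


def _background(rng, size: int, sigma_frac: float, noise: float):
    """Mucosa-like base: tinted low-frequency blur + fine noise."""
    low = ndimage.gaussian_filter(rng.standard_normal((size, size)),
                                  sigma=max(1.0, sigma_frac * size))
    low = low / (np.abs(low).max() + 1e-9)
    img = MUCOSA_RGB[None, None, :] * (1.0 + 0.25 * low[:, :, None])
    img = img + noise * rng.standard_normal((size, size, 3))
    return img


def _polar(size: int, cy: float, cx: float):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - cy, xx - cx
    return np.hypot(dy, dx), np.arctan2(dy, dx)


def _lesion_center(rng, size: int, margin: float):
    return (rng.uniform(margin, size - margin),
            rng.uniform(margin, size - margin))


def _esophagitis(rng, img, size):
    """Bright radial streaks emanating from a random center."""
    R = size * rng.uniform(0.25, 0.38)
    cy, cx = _lesion_center(rng, size, R * 0.7)
    rr, ang = _polar(size, cy, cx)
    n_streaks = rng.integers(5, 9)
    angles = rng.uniform(-np.pi, np.pi, size=n_streaks)
    width = rng.uniform(0.08, 0.14)
    streak = np.zeros((size, size))
    for a in angles:
        d = np.angle(np.exp(1j * (ang - a)))  # wrapped angular distance
        streak = np.maximum(streak, np.exp(-0.5 * (d / width) ** 2))
    radial = np.exp(-0.5 * (rr / R) ** 2)
    bump = (streak * radial)[:, :, None] * np.array([0.55, 0.5, 0.45])
    return img + bump


def _polyp(rng, img, size):
    """One smooth bright ellipsoidal dome with a specular highlight."""
    r0 = size * rng.uniform(0.16, 0.26)
    cy, cx = _lesion_center(rng, size, r0 * 1.2)
    ecc = rng.uniform(0.7, 1.0)
    phi = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - cy, xx - cx
    u = np.cos(phi) * dx + np.sin(phi) * dy
    v = -np.sin(phi) * dx + np.cos(phi) * dy
    q = (u / r0) ** 2 + (v / (ecc * r0)) ** 2
    dome = np.exp(-1.2 * q)
    hy, hx = cy - 0.3 * r0, cx - 0.3 * r0
    hl = np.exp(-0.5 * (((yy - hy) ** 2 + (xx - hx) ** 2) / (0.15 * r0) ** 2))
    bump = dome[:, :, None] * np.array([0.35, 0.32, 0.28]) \
        + hl[:, :, None] * 0.35
    return img + bump


def _colitis(rng, img, size):
    """Dense dark speckle field (granular, friable mucosa)."""
    R = size * rng.uniform(0.25, 0.38)
    cy, cx = _lesion_center(rng, size, R * 0.8)
    rr, _ = _polar(size, cy, cx)
    field = rng.random((size, size)) < 0.35
    speck = ndimage.gaussian_filter(field.astype(float), sigma=0.6)
    region = np.exp(-0.5 * (rr / R) ** 2)
    dark = (speck * region)[:, :, None] * np.array([0.45, 0.35, 0.3])
    return img - dark


_CLASS_PAINTERS = (_esophagitis, _polyp, _colitis)


def gen_classification(spec: SynthSpec):
    """Balanced 3-class lesion-texture set.

    Returns (images (n, S, S, 3) float in [0,1], labels (n,) int,
    class_names).  Classes are interleaved so any prefix is near-balanced.
    """
    if spec.task != "classification":
        raise ValidationError("spec.task must be 'classification'")
    if spec.n_per_class <= 0:
        raise ValidationError("n_per_class must be positive")
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    n = 3 * spec.n_per_class
    images = np.empty((n, size, size, 3))
    labels = np.empty(n, dtype=int)
    for i in range(n):
        cls = i % 3
        img = _background(rng, size, spec.background_sigma, spec.noise_level)
        img = _CLASS_PAINTERS[cls](rng, img, size)
        images[i] = np.clip(img, 0.0, 1.0)
        labels[i] = cls
    return images, labels, CLASS_NAMES


def perturbed_ellipse_mask(size, cy, cx, r0, amp, k, phase):
    """Rasterize r(phi) = r0 (1 + amp sin(k phi + phase)) around (cy, cx)."""
    rr, ang = _polar(size, cy, cx)
    rmax = r0 * (1.0 + amp * np.sin(k * ang + phase))
    return (rr <= rmax).astype(np.uint8)


def perturbed_ellipse_area(r0, amp):
    """Analytic area of the perturbed ellipse: pi r0^2 (1 + amp^2 / 2)."""
    return math.pi * r0 ** 2 * (1.0 + amp ** 2 / 2.0)


def gen_segmentation(spec: SynthSpec, max_retries: int = 50):
    """Images with 1-3 bright irregular blobs and exact binary masks.

    Returns (images (n, S, S, 3) in [0,1], masks (n, S, S) uint8 in {0,1}).
    Blobs that would overflow the frame are resampled, with a retry cap.
    """
    if spec.task != "segmentation":
        raise ValidationError("spec.task must be 'segmentation'")
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    n = spec.n_images
    lo, hi = spec.blob_count
    images = np.empty((n, size, size, 3))
    masks = np.zeros((n, size, size), dtype=np.uint8)
    for i in range(n):
        img = _background(rng, size, spec.background_sigma, spec.noise_level)
        n_blobs = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        for _ in range(n_blobs):
            for attempt in range(max_retries + 1):
                r0 = size * rng.uniform(*spec.radius_range)
                amp = rng.uniform(0.05, spec.irregularity)
                k = int(rng.integers(3, 8))
                phase = rng.uniform(0, 2 * np.pi)
                rmax = r0 * (1 + amp)
                if rmax >= size / 2 - 1:
                    if attempt == max_retries:
                        raise ValidationError(
                            "blob larger than frame after retry cap")
                    continue
                cy = rng.uniform(rmax + 1, size - rmax - 1)
                cx = rng.uniform(rmax + 1, size - rmax - 1)
                break
            blob = perturbed_ellipse_mask(size, cy, cx, r0, amp, k, phase)
            masks[i] |= blob
            rr, ang = _polar(size, cy, cx)
            redge = r0 * (1.0 + amp * np.sin(k * ang + phase))
            prof = np.clip(1.0 - rr / np.maximum(redge, 1e-9), 0.0, 1.0) ** 0.5
            img = img + (blob * prof)[:, :, None] * np.array([0.4, 0.38, 0.3])
        images[i] = np.clip(img, 0.0, 1.0)
    return images, masks


# ---------------------------------------------------------------------------
# augmentation

@dataclass(frozen=True)
class AugmentParams:
    """One concrete draw of the geometric augmentation."""

    angle: float = 0.0      # degrees
    flip_h: bool = False
    flip_v: bool = False
    shift_x: float = 0.0    # fraction of width
    shift_y: float = 0.0    # fraction of height
    shear: float = 0.0
    zoom: float = 0.0       # scale = 1 + zoom


DEFAULT_RANGES = dict(rotation=40.0, flip_prob=0.2, shift=0.2,
                      shear=0.1, zoom=0.1)


def draw_augment_params(rng, rotation=40.0, flip_prob=0.2, shift=0.2,
                        shear=0.1, zoom=0.1) -> AugmentParams:
    """One random draw within the training augmentation ranges."""
    return AugmentParams(
        angle=float(rng.uniform(-rotation, rotation)),
        flip_h=bool(rng.random() < flip_prob),
        flip_v=bool(rng.random() < flip_prob),
        shift_x=float(rng.uniform(-shift, shift)),
        shift_y=float(rng.uniform(-shift, shift)),
        shear=float(rng.uniform(-shear, shear)),
        zoom=float(rng.uniform(-zoom, zoom)),
    )


def augment_affine_matrix(p: AugmentParams, shape) -> np.ndarray:
    """Forward 3x3 homogeneous matrix mapping input (y, x, 1) to output.

    Rotation/shear/zoom/flips act about the image center; shifts are in
    pixels derived from the fractional parameters.
    """
    H, W = shape[:2]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    th = math.radians(p.angle)
    R = np.array([[math.cos(th), -math.sin(th)],
                  [math.sin(th), math.cos(th)]])
    Sh = np.array([[1.0, p.shear], [0.0, 1.0]])
    Z = (1.0 + p.zoom) * np.eye(2)
    F = np.diag([-1.0 if p.flip_v else 1.0, -1.0 if p.flip_h else 1.0])
    L = R @ Sh @ Z @ F
    t = np.array([p.shift_y * H, p.shift_x * W])
    c = np.array([cy, cx])
    M = np.eye(3)
    M[:2, :2] = L
    M[:2, 2] = c + t - L @ c
    return M


def _warp(arr, M_fwd, order, mode, cval=0.0):
    """Apply the forward map via scipy's inverse-map affine resampler."""
    Linv = np.linalg.inv(M_fwd[:2, :2])
    offset = -Linv @ M_fwd[:2, 2]
    if arr.ndim == 3:
        out = np.stack([
            ndimage.affine_transform(arr[..., c], Linv, offset=offset,
                                     order=order, mode=mode, cval=cval)
            for c in range(arr.shape[-1])], axis=-1)
    else:
        out = ndimage.affine_transform(arr, Linv, offset=offset,
                                       order=order, mode=mode, cval=cval)
    return out


def augment_pair(image, mask=None, params: AugmentParams | None = None,
                 rng=None, **ranges):
    """Apply one geometric augmentation draw to an image (and its mask).

    When ``params`` is None a fresh draw is taken from ``rng``.  The image
    is resampled bilinearly with reflect padding; the mask gets the
    identical transform with nearest-neighbour interpolation, zero padding
    and re-binarization, so image and mask stay geometrically consistent.
    """
    if params is None:
        if rng is None:
            raise ValidationError("need params or rng")
        params = draw_augment_params(rng, **{**DEFAULT_RANGES, **ranges})
    M = augment_affine_matrix(params, np.asarray(image).shape)
    out_img = _warp(np.asarray(image, dtype=float), M, order=1, mode="reflect")
    if mask is None:
        return out_img, None
    warped = _warp(np.asarray(mask, dtype=float), M, order=0,
                   mode="constant", cval=0.0)
    return out_img, (warped > 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# on-disk layouts (cross-tested with the engine loaders)

def _to_png(img):
    return np.clip(np.round(np.asarray(img) * 255.0), 0, 255).astype(np.uint8)


def save_classification_dataset(outdir, images, labels,
                                class_names=CLASS_NAMES):
    """Write the directory-per-class layout of PNG files."""
    import imageio.v3 as iio
    for name in class_names:
        os.makedirs(os.path.join(outdir, name), exist_ok=True)
    for i, (img, lab) in enumerate(zip(images, labels)):
        path = os.path.join(outdir, class_names[lab], f"img_{i:05d}.png")
        iio.imwrite(path, _to_png(img))
    return outdir


def save_segmentation_dataset(outdir, images, masks):
    """Write the paired images/ + masks/ layout (masks as 0/255 PNG)."""
    import imageio.v3 as iio
    os.makedirs(os.path.join(outdir, "images"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "masks"), exist_ok=True)
    for i, (img, m) in enumerate(zip(images, masks)):
        base = f"img_{i:05d}.png"
        iio.imwrite(os.path.join(outdir, "images", base), _to_png(img))
        iio.imwrite(os.path.join(outdir, "masks", base),
                    (np.asarray(m, dtype=np.uint8) * 255))
    return outdir
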