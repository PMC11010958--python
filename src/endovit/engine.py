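"""Dataset loading, train/eval loops and experiment plumbing.

Defaults follow the training recipe used throughout: Adam with learning
rate 1e-4, batch size 16, 50 epochs for classification and 150 for
segmentation, L2 weight decay on non-normalization weights, GELU
activations, 224x224 inputs, 9:1 (classification) and 8:2 (segmentation)
train/test splits, and online geometric augmentation of training batches.
Every source of randomness (weight init, shuffling, augmentation draws) is
derived from the run seed, so identical configs reproduce identical logs.
"""

from __future__ import annotations

import os
import pickle
from dataclasses import dataclass, field, replace

import numpy as np
from autograd import value_and_grad

from . import metrics as metrics_mod
from . import stn, swin, synthdata, vit
from .nn import Adam, ValidationError, l2_penalty, unbox

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


# ---------------------------------------------------------------------------
# manifests and loaders

@dataclass
class DatasetManifest:
    task: str                       # 'classification' | 'segmentation'
    items: list                     # (image_path, label) or (image, mask) paths
    class_names: tuple = ()
    input_size: int = 224

    def __len__(self):
        return len(self.items)


def _read_image(path, size, channels=3):
    from PIL import Image
    try:
        with Image.open(path) as im:
            im = im.convert("RGB" if channels == 3 else "L")
            im = im.resize((size, size), Image.BILINEAR)
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except Exception as exc:
        raise ValidationError(f"cannot decode image file {path!r}: {exc}") from exc
    if channels == 3 and arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return arr


def _read_mask(path, size):
    """Grayscale or RGB mask file -> binary (size, size) array (>127 -> 1)."""
    from PIL import Image
    try:
        with Image.open(path) as im:
            im = im.convert("L")
            im = im.resize((size, size), Image.NEAREST)
            arr = np.asarray(im)
    except Exception as exc:
        raise ValidationError(f"cannot decode mask file {path!r}: {exc}") from exc
    return (arr > 127).astype(np.uint8)


def load_class_dataset(root, input_size: int = 224) -> DatasetManifest:
    """Directory-per-class layout -> manifest with deterministic
    (lexicographic) item order; verifies every file decodes."""
    classes = sorted(d for d in os.listdir(root)
                     if os.path.isdir(os.path.join(root, d)))
    if not classes:
        raise ValidationError(f"no class subdirectories under {root!r}")
    items = []
    for ci, cname in enumerate(classes):
        files = sorted(f for f in os.listdir(os.path.join(root, cname))
                       if f.lower().endswith(IMAGE_EXTENSIONS))
        if not files:
            raise ValidationError(f"class folder {cname!r} is empty")
        bad = sorted(f for f in os.listdir(os.path.join(root, cname))
                     if not f.lower().endswith(IMAGE_EXTENSIONS)
                     and not f.startswith("."))
        if bad:
            raise ValidationError(
                f"non-image file(s) in class {cname!r}: {bad}")
        items.extend((os.path.join(root, cname, f), ci) for f in files)
    return DatasetManifest(task="classification", items=items,
                           class_names=tuple(classes), input_size=input_size)


def load_seg_dataset(root, input_size: int = 224) -> DatasetManifest:
    """images/ + masks/ layout with matching basenames -> paired manifest."""
    img_dir = os.path.join(root, "images")
    mask_dir = os.path.join(root, "masks")
    imgs = {os.path.splitext(f)[0]: f for f in sorted(os.listdir(img_dir))
            if f.lower().endswith(IMAGE_EXTENSIONS)}
    masks = {os.path.splitext(f)[0]: f for f in sorted(os.listdir(mask_dir))
             if f.lower().endswith(IMAGE_EXTENSIONS)}
    orphans = sorted(set(imgs) ^ set(masks))
    if orphans:
        raise ValidationError(f"unmatched image/mask basenames: {orphans}")
    items = [(os.path.join(img_dir, imgs[k]), os.path.join(mask_dir, masks[k]))
             for k in sorted(imgs)]
    if not items:
        raise ValidationError(f"no image/mask pairs under {root!r}")
    return DatasetManifest(task="segmentation", items=items,
                           input_size=input_size)


def manifest_arrays(manifest: DatasetManifest):
    """Materialize a manifest: images scaled to [0,1] and resized; masks
    binarized at >127 (nearest-neighbour resize)."""
    s = manifest.input_size
    images = np.stack([_read_image(p, s) for p, _ in manifest.items])
    if manifest.task == "classification":
        labels = np.array([lab for _, lab in manifest.items], dtype=int)
        return images, labels
    masks = np.stack([_read_mask(mp, s) for _, mp in manifest.items])
    return images, masks


def split(manifest: DatasetManifest, ratio: float, seed: int):
    """Seeded shuffle-then-split; stratified per class for classification.

    Returns (train_manifest, test_manifest); disjointness is guaranteed by
    construction and asserted.
    """
    if not 0.0 < ratio < 1.0:
        raise ValidationError("split ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    items = manifest.items
    if manifest.task == "classification":
        train_idx, test_idx = [], []
        labels = np.array([lab for _, lab in items])
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            if idx.size < 2:
                raise ValidationError(
                    f"class {cls} has {idx.size} item(s); cannot stratify")
            idx = rng.permutation(idx)
            cut = int(round(ratio * idx.size))
            cut = min(max(cut, 1), idx.size - 1)
            train_idx.extend(idx[:cut])
            test_idx.extend(idx[cut:])
        train_idx, test_idx = sorted(train_idx), sorted(test_idx)
    else:
        idx = rng.permutation(len(items))
        cut = int(round(ratio * len(items)))
        train_idx, test_idx = sorted(idx[:cut]), sorted(idx[cut:])
    assert not set(train_idx) & set(test_idx), "train/test overlap"
    mk = lambda sel: replace(manifest, items=[items[i] for i in sel])
    return mk(train_idx), mk(test_idx)


def split_arrays(images, targets, ratio: float, seed: int,
                 stratify: bool = False):
    """Array-level counterpart of :func:`split` for in-memory datasets."""
    if not 0.0 < ratio < 1.0:
        raise ValidationError("split ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(images)
    if stratify:
        labels = np.asarray(targets)
        tr, te = [], []
        for cls in np.unique(labels):
            idx = rng.permutation(np.flatnonzero(labels == cls))
            cut = int(round(ratio * idx.size))
            cut = min(max(cut, 1), idx.size - 1)
            tr.extend(idx[:cut])
            te.extend(idx[cut:])
        tr, te = np.array(sorted(tr)), np.array(sorted(te))
    else:
        idx = rng.permutation(n)
        cut = int(round(ratio * n))
        tr, te = np.sort(idx[:cut]), np.sort(idx[cut:])
    return (images[tr], np.asarray(targets)[tr],
            images[te], np.asarray(targets)[te])


# ---------------------------------------------------------------------------
# run configuration and optimizers

@dataclass(frozen=True)
class RunConfig:
    """Training hyperparameters (defaults = the package's standard recipe)."""

    task: str = "classification"
    model: str = "vitb_16"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int | None = None       # 50 classification / 150 segmentation
    l2: float = 1e-4
    augment: bool = True
    split_ratio: float | None = None  # 0.9 classification / 0.8 segmentation
    seed: int = 0
    input_size: int = 224
    outdir: str | None = None
    eval_every: int = 0             # epochs between in-training evals (0 = off)
    keep_best: bool = False         # retain best-by-validation checkpoint
    val_fraction: float = 0.1
    stop_at_metric: float | None = None  # early exit once eval metric reached

    def resolved(self) -> "RunConfig":
        epochs = self.epochs if self.epochs is not None else (
            50 if self.task == "classification" else 150)
        ratio = self.split_ratio if self.split_ratio is not None else (
            0.9 if self.task == "classification" else 0.8)
        return replace(self, epochs=epochs, split_ratio=ratio)


class _SGD:
    def __init__(self, params, lr):
        from autograd.misc import flatten
        self.x, self._unflatten = flatten(params)
        self.lr = lr

    @property
    def params(self):
        return self._unflatten(self.x)

    def step(self, grads):
        from autograd.misc import flatten
        g, _ = flatten(grads)
        self.x = self.x - self.lr * g
        return self.params


class _Adagrad(_SGD):
    def __init__(self, params, lr):
        super().__init__(params, lr)
        self.g2 = np.zeros_like(self.x)

    def step(self, grads):
        from autograd.misc import flatten
        g, _ = flatten(grads)
        self.g2 += g ** 2
        self.x = self.x - self.lr * g / (np.sqrt(self.g2) + 1e-8)
        return self.params


class _Adadelta(_SGD):
    def __init__(self, params, lr, rho=0.95):
        super().__init__(params, lr)
        self.rho = rho
        self.eg2 = np.zeros_like(self.x)
        self.edx2 = np.zeros_like(self.x)

    def step(self, grads):
        from autograd.misc import flatten
        g, _ = flatten(grads)
        self.eg2 = self.rho * self.eg2 + (1 - self.rho) * g ** 2
        dx = -np.sqrt(self.edx2 + 1e-6) / np.sqrt(self.eg2 + 1e-6) * g
        self.edx2 = self.rho * self.edx2 + (1 - self.rho) * dx ** 2
        self.x = self.x + self.lr * dx
        return self.params


class _Adamax(Adam):
    def step(self, grads):
        from autograd.misc import flatten
        g, _ = flatten(grads)
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * g
        self.v = np.maximum(self.b2 * self.v, np.abs(g))
        self.x = self.x - (self.lr / (1 - self.b1 ** self.t)) * self.m \
            / (self.v + self.eps)
        return self.params


OPTIMIZERS = {"adam": Adam, "sgd": _SGD, "adagrad": _Adagrad,
              "adadelta": _Adadelta, "adamax": _Adamax}


def make_optimizer(name: str, params, lr: float):
    if name not in OPTIMIZERS:
        raise ValidationError(
            f"unknown optimizer {name!r}; have {sorted(OPTIMIZERS)}")
    return OPTIMIZERS[name](params, lr=lr)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainResult:
    params: dict
    config: RunConfig
    log: list = field(default_factory=list)
    bn_state: dict | None = None
    best_params: dict | None = None
    best_metric: float | None = None


def _augment_batch(xb, yb, rng, task):
    out_x = np.empty_like(xb)
    if task == "segmentation":
        out_y = np.empty_like(yb)
        for i in range(len(xb)):
            out_x[i], out_y[i] = synthdata.augment_pair(xb[i], yb[i], rng=rng)
        return out_x, out_y
    for i in range(len(xb)):
        out_x[i], _ = synthdata.augment_pair(xb[i], rng=rng)
    return out_x, yb


def _check_finite(loss_val, epoch, batch):
    if not np.isfinite(loss_val):
        raise FloatingPointError(
            f"non-finite training loss at epoch {epoch}, batch {batch}: "
            f"{loss_val!r}")


def compute_bn_state(params, cfg, images, batch_size: int = 64):
    """Running statistics of the pre-batch-norm class-token features over a
    reference set (used for deterministic inference)."""
    feats = []
    for s in range(0, len(images), batch_size):
        tokens = vit.encode(images[s:s + batch_size], cfg, params)
        feats.append(unbox(tokens)[:, 0, :])
    feats = np.concatenate(feats)
    return {"mean": feats.mean(axis=0), "var": feats.var(axis=0)}


def train_classifier(images, labels, model_cfg: vit.ViTConfig,
                     run: RunConfig, eval_data=None,
                     params=None) -> TrainResult:
    """Minimize multiclass cross-entropy with the configured optimizer.

    ``eval_data``: optional (images, labels) evaluated every
    ``run.eval_every`` epochs; the best-accuracy checkpoint is retained
    when ``run.keep_best``.  Fully seeded: weight init, data order and
    augmentation draws all derive from ``run.seed``.
    """
    run = replace(run, task="classification").resolved()
    rng = np.random.default_rng(run.seed)
    aug_rng = np.random.default_rng(rng.integers(2 ** 31))
    if params is None:
        params = vit.init_vitcol_params(model_cfg, rng)
    opt = make_optimizer(run.optimizer, params, run.learning_rate)
    labels = np.asarray(labels, dtype=int)

    def loss_fn(p, xb, yb):
        logits = vit.vitcol_forward(xb, model_cfg, p, return_logits=True)
        return vit.cross_entropy(logits, yb) + run.l2 * l2_penalty(p)

    loss_grad = value_and_grad(loss_fn)
    result = TrainResult(params=params, config=run)
    n = len(images)
    for epoch in range(run.epochs):
        order = rng.permutation(n)
        ep_losses = []
        for bi, s in enumerate(range(0, n, run.batch_size)):
            sel = order[s:s + run.batch_size]
            xb, yb = images[sel], labels[sel]
            if run.augment:
                xb, yb = _augment_batch(xb, yb, aug_rng, "classification")
            lval, g = loss_grad(opt.params, xb, yb)
            lval = float(unbox(lval))
            _check_finite(lval, epoch, bi)
            ep_losses.append(lval)
            params = opt.step(g)
        row = {"epoch": epoch, "train_loss": float(np.mean(ep_losses))}
        if eval_data is not None and run.eval_every and \
                (epoch + 1) % run.eval_every == 0:
            bn_state = compute_bn_state(params, model_cfg, images)
            report = evaluate_classifier(params, model_cfg, *eval_data,
                                         bn_state=bn_state, seed=run.seed)
            row["eval_accuracy"] = report["accuracy"]
            if run.keep_best and (result.best_metric is None
                                  or report["accuracy"] > result.best_metric):
                result.best_metric = report["accuracy"]
                result.best_params = _copy_params(params)
            if run.stop_at_metric is not None and \
                    report["accuracy"] >= run.stop_at_metric:
                result.log.append(row)
                break
        result.log.append(row)
    result.params = params
    result.bn_state = compute_bn_state(params, model_cfg, images) \
        if run.epochs > 0 and n > 0 else None
    return result


def train_segmenter(images, masks, model_cfg: swin.SwinConfig,
                    run: RunConfig, eval_data=None,
                    params=None) -> TrainResult:
    """Minimize the pixel-wise categorical cross-entropy; seeded as above.

    ``eval_data``: optional (images, masks) pair; the best-mDice checkpoint
    is retained when ``run.keep_best``.
    """
    run = replace(run, task="segmentation").resolved()
    rng = np.random.default_rng(run.seed)
    aug_rng = np.random.default_rng(rng.integers(2 ** 31))
    if params is None:
        params = swin.init_puts_params(model_cfg, rng)
    opt = make_optimizer(run.optimizer, params, run.learning_rate)
    masks = np.asarray(masks)

    def loss_fn(p, xb, yb):
        logits = swin.puts_logits(xb, model_cfg, p)
        return swin.seg_loss_from_logits(logits, yb) + run.l2 * l2_penalty(p)

    loss_grad = value_and_grad(loss_fn)
    result = TrainResult(params=params, config=run)
    n = len(images)
    for epoch in range(run.epochs):
        order = rng.permutation(n)
        ep_losses = []
        for bi, s in enumerate(range(0, n, run.batch_size)):
            sel = order[s:s + run.batch_size]
            xb, yb = images[sel], masks[sel]
            if run.augment:
                xb, yb = _augment_batch(xb, yb, aug_rng, "segmentation")
            lval, g = loss_grad(opt.params, xb, yb)
            lval = float(unbox(lval))
            _check_finite(lval, epoch, bi)
            ep_losses.append(lval)
            params = opt.step(g)
        row = {"epoch": epoch, "train_loss": float(np.mean(ep_losses))}
        if eval_data is not None and run.eval_every and \
                (epoch + 1) % run.eval_every == 0:
            report, _ = evaluate_segmenter(params, model_cfg, *eval_data,
                                           seed=run.seed)
            row["eval_miou"] = report["miou"]
            row["eval_mdice"] = report["mdice"]
            if run.keep_best and (result.best_metric is None
                                  or report["mdice"] > result.best_metric):
                result.best_metric = report["mdice"]
                result.best_params = _copy_params(params)
            if run.stop_at_metric is not None and \
                    report["miou"] >= run.stop_at_metric:
                result.log.append(row)
                break
        result.log.append(row)
    result.params = params
    return result


def _copy_params(params):
    from autograd.misc import flatten
    flat, unflat = flatten(params)
    return unflat(flat.copy())


# ---------------------------------------------------------------------------
# evaluation / prediction

def predict_proba(params, cfg, images, bn_state=None, batch_size: int = 64):
    """Deterministic class probabilities (no augmentation, no dropout)."""
    out = []
    for s in range(0, len(images), batch_size):
        out.append(unbox(vit.vitcol_forward(images[s:s + batch_size], cfg,
                                            params, bn_state=bn_state)))
    return np.concatenate(out)


def evaluate_classifier(params, cfg, images, labels, bn_state=None,
                        seed=None) -> metrics_mod.MetricsReport:
    proba = predict_proba(params, cfg, images, bn_state=bn_state)
    return metrics_mod.classification_report(labels, proba, seed=seed)


def predict_soft_masks(params, cfg, images, batch_size: int = 16):
    out = []
    for s in range(0, len(images), batch_size):
        out.append(unbox(swin.puts_forward(images[s:s + batch_size], cfg,
                                           params)))
    return np.concatenate(out)


def evaluate_segmenter(params, cfg, images, masks, seed=None):
    """MetricsReport plus the hard predicted masks."""
    soft = predict_soft_masks(params, cfg, images)
    hard = swin.hard_mask(soft)
    report = metrics_mod.segmentation_report(list(np.asarray(masks)),
                                             list(hard), seed=seed)
    return report, hard


def export_masks(masks, outdir, basenames=None):
    """Write hard masks as 8-bit 0/255 PNG files; returns the paths."""
    import imageio.v3 as iio
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for i, m in enumerate(masks):
        base = basenames[i] if basenames is not None else f"mask_{i:05d}.png"
        base = os.path.splitext(os.path.basename(base))[0] + ".png"
        path = os.path.join(outdir, base)
        iio.imwrite(path, (np.asarray(m, dtype=np.uint8) * 255))
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, params, model_cfg, run: RunConfig, extra=None):
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump({"params": params, "model_cfg": model_cfg,
                     "run": run, "extra": extra or {}}, fh)


def load_checkpoint(path):
    with open(path, "rb") as fh:
        return pickle.load(fh)


# ---------------------------------------------------------------------------
# ablation harness

def run_ablation_classification(images, labels, model_cfg, run: RunConfig,
                                eval_data):
    """Train the classifier with and without the spatial transformer under
    identical seeds/configs; returns the paired reports."""
    reports = {}
    for tag, use_stn in (("with_stn", True), ("without_stn", False)):
        cfg = replace(model_cfg, use_stn=use_stn)
        res = train_classifier(images, labels, cfg, run)
        reports[tag] = evaluate_classifier(res.params, cfg, *eval_data,
                                           bn_state=res.bn_state,
                                           seed=run.seed)
    return reports


def run_ablation_segmentation(images, masks, model_cfg, run: RunConfig,
                              eval_data):
    """Same paired comparison for the segmenter (Swin-Unet vs PUTS)."""
    reports = {}
    for tag, use_stn in (("with_stn", True), ("without_stn", False)):
        cfg = replace(model_cfg, use_stn=use_stn)
        res = train_segmenter(images, masks, cfg, run)
        reports[tag], _ = evaluate_segmenter(res.params, cfg, *eval_data,
                                             seed=run.seed)
    return reports
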