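"""Evaluation metrics for lesion classification and polyp segmentation.

Classification: accuracy, macro one-vs-rest AUC, macro-averaged sensitivity
(recall), specificity and F1, multiclass Matthews correlation coefficient,
and Cohen's kappa.  The single headline sensitivity/specificity/F1 numbers
reported for a multiclass task are macro averages; micro averages are also
emitted in the per-class breakdown.

Segmentation: per-image IoU and Dice averaged over the evaluation set
(mIoU, mDice — the dominant convention in the polyp-segmentation
literature), plus pixel-level sensitivity, specificity and MCC pooled over
all evaluated pixels.

AUC, multiclass MCC and Cohen's kappa are delegated to scikit-learn; the
confusion-matrix-derived scores are computed directly from their
definitions.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef, roc_auc_score

from .nn import ValidationError

__version__ = "0.1.0"


@dataclass
class MetricsReport:
    """Named scalar scores for one evaluation run, with provenance fields."""

    task: str
    scores: dict
    n: int
    per_class: dict = field(default_factory=dict)
    seed: int | None = None
    config_hash: str | None = None
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "task": self.task, "n": self.n, "scores": self.scores,
            "per_class": self.per_class, "seed": self.seed,
            "config_hash": self.config_hash, "version": self.version,
        }

    def to_json(self, path=None, indent=2) -> str:
        s = json.dumps(self.to_dict(), indent=indent, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def to_csv_row(self, path) -> None:
        """Append one flat row (scores + provenance) to a CSV file."""
        row = {"task": self.task, "n": self.n, "seed": self.seed,
               "config_hash": self.config_hash, "version": self.version}
        row.update({k: float(v) for k, v in self.scores.items()})
        new = not _file_has_content(path)
        with open(path, "a", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(row))
            if new:
                w.writeheader()
            w.writerow(row)

    def __getitem__(self, key):
        return self.scores[key]


def _file_has_content(path) -> bool:
    try:
        with open(path) as fh:
            return bool(fh.read(1))
    except FileNotFoundError:
        return False


def config_hash(obj) -> str:
    """Short stable hash of a configuration object for report provenance."""
    s = json.dumps(obj, sort_keys=True, default=repr) \
        if not isinstance(obj, str) else obj
    return hashlib.sha256(s.encode()).hexdigest()[:12]


def confusion_matrix(y_true, y_pred, num_classes: int) -> np.ndarray:
    """K x K counts, rows = truth, columns = prediction."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label arrays differ in length")
    cm = np.zeros((num_classes, num_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def labels_from_confusion(cm) -> tuple[np.ndarray, np.ndarray]:
    """Expand a confusion matrix into (y_true, y_pred) label vectors."""
    cm = np.asarray(cm, dtype=int)
    yt, yp = [], []
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            yt.extend([i] * cm[i, j])
            yp.extend([j] * cm[i, j])
    return np.array(yt), np.array(yp)


def _binary_rates(tp, fn, fp, tn):
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    f1 = (2 * prec * sens / (prec + sens)
          if (prec + sens) and np.isfinite(prec + sens) and prec + sens > 0
          else 0.0)
    return sens, spec, prec, f1


def classification_report(y_true, proba, num_classes: int | None = None,
                          on_missing_class: str = "raise",
                          seed: int | None = None,
                          config=None) -> MetricsReport:
    """Full classification score set from true labels and predicted
    class-probability rows.

    ``on_missing_class``: 'raise' errors when a class is absent from the
    truth (macro averages would be ill-defined); 'nan' emits NaN for the
    affected macro scores with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    if y_true.size == 0:
        raise ValidationError("empty evaluation set")
    if proba.ndim != 2 or proba.shape[0] != y_true.shape[0]:
        raise ValidationError("probability array must be (n, K)")
    K = num_classes or proba.shape[1]
    if K < 2:
        raise ValidationError("need at least 2 classes")
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-5):
        raise ValidationError("probability rows must sum to 1")
    present = np.unique(y_true)
    missing = sorted(set(range(K)) - set(present.tolist()))
    if missing:
        if on_missing_class == "raise":
            raise ValidationError(
                f"classes {missing} absent from truth; macro averages "
                "undefined (pass on_missing_class='nan' to continue)")
        warnings.warn(f"classes {missing} absent from truth; emitting NaN")

    y_pred = proba.argmax(axis=1)
    cm = confusion_matrix(y_true, y_pred, K)
    n = int(cm.sum())
    accuracy = float(np.trace(cm)) / n

    per_class = {}
    sens_list, spec_list, f1_list = [], [], []
    for k in range(K):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = n - tp - fn - fp
        sens, spec, prec, f1 = _binary_rates(tp, fn, fp, tn)
        per_class[k] = {"sensitivity": sens, "specificity": spec,
                        "precision": prec, "f1": f1,
                        "support": int(cm[k].sum())}
        sens_list.append(sens)
        spec_list.append(spec)
        f1_list.append(f1)

    # micro averages (pooled one-vs-rest counts) for the breakdown
    tp_all = np.trace(cm)
    micro_sens = tp_all / n  # == accuracy for single-label multiclass

    if missing:
        auc = mcc = kappa = float("nan")
        macro_sens = macro_spec = macro_f1 = float("nan")
    else:
        macro_sens = float(np.nanmean(sens_list))
        macro_spec = float(np.nanmean(spec_list))
        macro_f1 = float(np.nanmean(f1_list))
        if K == 2:
            auc = float(roc_auc_score(y_true, proba[:, 1]))
        else:
            auc = float(roc_auc_score(y_true, proba, multi_class="ovr",
                                      average="macro", labels=np.arange(K)))
        mcc = float(matthews_corrcoef(y_true, y_pred))
        kappa = float(cohen_kappa_score(y_true, y_pred))

    scores = {"accuracy": accuracy, "auc": auc, "sensitivity": macro_sens,
              "specificity": macro_spec, "f1": macro_f1, "mcc": mcc,
              "kappa": kappa}
    per_class["micro"] = {"sensitivity": float(micro_sens)}
    return MetricsReport(task="classification", scores=scores, n=n,
                         per_class=per_class, seed=seed,
                         config_hash=config_hash(config) if config else None)


def iou_dice(truth, pred, empty_value: float = 1.0):
    """Per-image IoU and Dice for one binary mask pair.

    ``empty_value`` defines the score when both masks are empty (default 1:
    a correct all-background prediction is perfect).
    """
    t = np.asarray(truth).astype(bool)
    p = np.asarray(pred).astype(bool)
    if t.shape != p.shape:
        raise ValidationError("mask shapes differ")
    inter = np.logical_and(t, p).sum()
    union = np.logical_or(t, p).sum()
    tsum, psum = t.sum(), p.sum()
    if union == 0:
        return empty_value, empty_value
    iou = inter / union
    dice = 2 * inter / (tsum + psum)
    return float(iou), float(dice)


def _check_binary(a, name):
    vals = np.unique(np.asarray(a))
    if not np.all(np.isin(vals, (0, 1, True, False))):
        raise ValidationError(f"{name} masks must be binary, found {vals[:8]}")


def segmentation_report(true_masks, pred_masks, empty_value: float = 1.0,
                        seed: int | None = None, config=None) -> MetricsReport:
    """mIoU/mDice (mean of per-image scores) plus pooled pixel-level
    sensitivity, specificity and MCC over the whole evaluation set."""
    true_masks = list(true_masks)
    pred_masks = list(pred_masks)
    if len(true_masks) != len(pred_masks) or not true_masks:
        raise ValidationError("need equal, non-zero numbers of mask pairs")
    _check_binary(np.concatenate([np.ravel(m) for m in true_masks]), "truth")
    _check_binary(np.concatenate([np.ravel(m) for m in pred_masks]), "prediction")

    ious, dices = [], []
    tp = fp = fn = tn = 0
    for t, p in zip(true_masks, pred_masks):
        i, d = iou_dice(t, p, empty_value=empty_value)
        ious.append(i)
        dices.append(d)
        tb = np.asarray(t).astype(bool)
        pb = np.asarray(p).astype(bool)
        tp += np.sum(tb & pb)
        fp += np.sum(~tb & pb)
        fn += np.sum(tb & ~pb)
        tn += np.sum(~tb & ~pb)
    sens, spec, _, _ = _binary_rates(tp, fn, fp, tn)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    scores = {"miou": float(np.mean(ious)), "mdice": float(np.mean(dices)),
              "sensitivity": float(sens), "specificity": float(spec),
              "mcc": float(mcc)}
    per_image = {"iou": [float(x) for x in ious],
                 "dice": [float(x) for x in dices]}
    return MetricsReport(task="segmentation", scores=scores,
                         n=len(true_masks), per_class=per_image, seed=seed,
                         config_hash=config_hash(config) if config else None)


def bootstrap_ci(values, n_boot: int = 1000, alpha: float = 0.05,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean of per-item scores (an artifact
    convention for interval reporting; seeded and resample-count-explicit)."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    means = rng.choice(values, size=(n_boot, values.size),
                       replace=True).mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
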