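"""The metric surface, from raw predictions to serialized reports.

Builds a classification report from a known confusion matrix, shows the
Dice/IoU relationship on a worked rectangle example, and demonstrates the
bootstrap interval over per-image scores.
"""

import numpy as np

from endovit import metrics

# classification: a fixed confusion matrix expanded back into labels
cm = np.array([[8, 1, 1], [2, 7, 1], [0, 2, 8]])
y_true, y_pred = metrics.labels_from_confusion(cm)
proba = np.full((len(y_pred), 3), 0.05)
proba[np.arange(len(y_pred)), y_pred] = 0.9
rep = metrics.classification_report(y_true, proba, 3, seed=0,
                                    config={"example": "metrics tour"})
print(rep.to_json())

# segmentation: two 2x4 rectangles overlapping in a 2x2 square
truth = np.zeros((8, 8), dtype=int)
pred = np.zeros((8, 8), dtype=int)
truth[3:5, 1:5] = 1
pred[3:5, 3:7] = 1
iou, dice = metrics.iou_dice(truth, pred)
print(f"rectangle example: IoU={iou:.4f} (1/3), Dice={dice:.4f} (1/2)")
print("identity check: 2*IoU/(1+IoU) =", 2 * iou / (1 + iou))

# uncertainty on per-image scores
rng = np.random.default_rng(0)
per_image_dice = np.clip(rng.normal(0.85, 0.06, size=40), 0, 1)
lo, hi = metrics.bootstrap_ci(per_image_dice, seed=0)
print(f"mean Dice {per_image_dice.mean():.3f}, 95% CI [{lo:.3f}, {hi:.3f}]")
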