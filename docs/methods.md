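# Methods

This note describes what the package computes and why, in enough detail to
re-derive every tested quantity independently.

## Problem setting

Two tasks from gastrointestinal endoscopy:

1. **Lesion classification.** Assign each endoscopic frame to one of three
   pathological findings (esophagitis, polyps, ulcerative colitis).
2. **Polyp segmentation.** Produce a per-pixel binary mask separating polyp
   tissue from background mucosa.

Both models share a front end: a **spatial transformer** that learns, with no
extra supervision, an affine re-framing of the input that concentrates the
downstream network's capacity on the lesion.

## Spatial transformer (`endovit.stn`)

Three differentiable pieces:

- **Localization network.** Two strided 2×2 convolution + GELU blocks
  (implemented exactly as space-to-depth reshapes followed by dense layers),
  global average pooling, and two dense layers regressing the six affine
  parameters θ. The final layer is initialized to zero weights with bias
  (1, 0, 0, 0, 1, 0), so a *fresh network always predicts the identity
  transform* — the module can only help, never hurt, at initialization.
- **Grid generator.** For every target pixel, normalized coordinates
  (x_t, y_t) ∈ [−1, 1]² (align-corners convention: ±1 are the centers of the
  border pixels) are mapped to source coordinates by
  x_s = θ₁₁x_t + θ₁₂y_t + θ₁₃ and y_s = θ₂₁x_t + θ₂₂y_t + θ₂₃.
- **Bilinear sampler.** Each output pixel is the bilinear interpolation of
  the four source neighbours, with zero padding outside the frame. Corner
  *indices* are piecewise constant in the inputs and are computed on concrete
  values; the interpolation *weights* stay on the autodiff tape, so the
  sampler is differentiable in both the image and the grid (hence in θ).

## Classifier (`endovit.vit`)

A standard vision transformer reading the spatially transformed image:
non-overlapping P×P patches flattened row-major, a linear patch embedding, a
learnable class token at position 0, learnable positional embeddings, and L
pre-norm encoder blocks

    x ← x + MSA(LN(x));   x ← x + MLP(LN(x))   (GELU inside the MLP),

followed by a final layer norm and a head (batch norm → dense → softmax) that
reads **only the class token**. Presets mirror the standard family:
`vitb_16` (12 layers, hidden 768, MLP 3072, 12 heads; 86M parameters with a
1000-way head), `vitb_32`, and `vitl_32` (24 layers, 1024, 4096, 16 heads).
Training minimizes multiclass cross-entropy in log-sum-exp form. The head's
batch norm uses batch statistics during training and frozen running statistics
(computed over the training set after the last step) at inference, so
evaluation is deterministic and batch-size independent.

## Segmenter (`endovit.swin`)

A U-shaped encoder–decoder of Swin transformer blocks behind the same spatial
transformer front end. 4×4 patch embedding produces a token grid; blocks come
in pairs — window attention (W-MSA) restricted to non-overlapping M×M
windows, then shifted-window attention (SW-MSA) on windows displaced by
⌊M/2⌋ with a cyclic shift and an additive mask (−10⁹ on logits) that forbids
attention between tokens that were not contiguous before the shift. Window
attention adds a learned **relative position bias**: one scalar per head per
relative offset, gathered from a (2M−1)²-entry table, inside the softmax:
softmax(QKᵀ/√d + B)V.

Resolution moves by **patch merging** (concatenate each 2×2 neighbourhood,
layer norm, linear 4d→2d) on the way down and **patch expanding** (linear
projection then pixel-shuffle; factor 2 halves the channel dim, the final
factor 4 preserves it) on the way up. Skip connections concatenate encoder
features with the decoder stream at matching resolution, followed by a linear
projection back to the stage width. A per-pixel linear head and a 2-class
softmax give the probability map; the hard mask is the argmax. Training
minimizes per-pixel categorical cross-entropy.

## Initialization

All transformer blocks (both models) zero the output weight of the attention
projection and of the second MLP layer, making each fresh block an exact
identity map over tokens; the segmenter's per-pixel head is also
zero-initialized, so the fresh model predicts 0.5/0.5 everywhere (loss exactly
ln 2). This removes an early training plateau in which the randomly-headed
segmenter collapses to all-background predictions for many epochs, and it
makes useful exact contracts testable (fresh model = identity / uniform).

## Training recipe (`endovit.engine`)

Adam (lr 1e-4, β = 0.9/0.999) by default, with SGD, Adagrad, Adadelta and
Adamax available; batch size 16; 50 epochs for classification, 150 for
segmentation; L2 penalty 1e-4 on weight matrices only (biases, norm gains and
embeddings excluded); stratified 9:1 train/test split for classification and
8:2 for segmentation. Online augmentation draws one random affine per training
image: rotation ±40°, horizontal/vertical flips (p = 0.2 each), shifts ±0.2 of
the dimension, shear ±0.1, zoom ±0.1 — applied bilinearly with reflect padding
to images and with nearest-neighbour resampling, zero padding, and
re-binarization to masks. Every random stream (weight init, shuffling,
augmentation) derives from the single run seed, so runs reproduce exactly.

## Metrics (`endovit.metrics`)

Classification: accuracy, macro-averaged one-vs-rest sensitivity, specificity
and F1 computed directly from the confusion matrix; macro one-vs-rest AUC,
multiclass Matthews correlation and Cohen's kappa via scikit-learn. The tests
re-derive all of these from their textbook definitions on a fixed confusion
matrix. Segmentation: per-image IoU and Dice averaged over the set (mIoU,
mDice), plus sensitivity, specificity and MCC pooled over all pixels. Two
empty masks score 1 by default (configurable). Dice and IoU satisfy
Dice = 2·IoU/(1 + IoU) identically, which the tests check per image.

## Synthetic fixtures (`endovit.synthdata`)

Seeded generators emulate the two dataset layouts at desk scale without
photorealism claims. Classification: three separable lesion textures (radial
streaks / bright dome with a specular highlight / dark speckle field) on a
mucosa-like low-frequency background, placed at random positions so the
spatial transformer has something to localize. Segmentation: 1–3 bright
irregular blobs with boundary r(φ) = r₀(1 + a·sin(kφ + φ₀)); the mask is the
exact rasterized interior, and the enclosed area has the closed form
πr₀²(1 + a²/2) used as an analytic oracle. Identical spec + seed gives
byte-identical arrays.

## Verification strategy

Every numeric claim is tested against an independent oracle: scalar-loop
re-implementations of the grid, sampler and attention; closed-form losses
(ln 3, ln 2); from-definition metric computations; analytic blob areas;
exactness of structural round trips; and equality (≤1e−6) between each
STN-fronted model with θ forced to identity and its plain backbone with shared
weights. Two seeded learning tests confirm that training actually works:
the tiny classifier reaches ≥0.95 held-out accuracy within 30 epochs and the
tiny segmenter reaches mIoU ≥0.85 within 40 epochs, both on one CPU.
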