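# Methods

## Problem and model

`endofew` addresses few-shot classification of colorectal polyp images
(e.g. NICE type I, hyperplastic-like, versus NICE type II,
adenoma-like), where the labelled cohort is tiny — often a single image
per polyp specimen.  Instead of training a classifier end-to-end, an
embedding model f: R^m → R^n (n ≪ m) is trained by deep metric
learning so that l2 distance in the n-dimensional latent space reflects
class-relevant similarity; simple discriminators then classify from a
handful of embedded examples.

The encoder is trained on (anchor, positive, negative) triplets with
the contrastive triplet loss

    L(x, x+, x-) = ‖f(x) − f(x+)‖₂ + max(0, m − ‖f(x) − f(x-)‖₂),

with margin m = 20.  The margin caps the reward for pushing negatives
ever further away, which prevents the degenerate norm-inflation
solution.  Embeddings are deliberately **not** length-normalised: the
margin is an absolute l2 distance and would be meaningless on the unit
sphere.  The three triplet branches share weights — implemented as one
network applied three times, which is mathematically identical to three
clones.

Training regimes for triplet construction:

* **supervised (fine-tuning)** — positive shares the anchor's class,
  negative comes from another class; used on the labelled polyp images.
* **multilabel (texture pretraining)** — for corpora whose images carry
  label *sets*, the positive shares at least one label with the anchor
  and the negative is completely class-disjoint from it.
* **self-supervised** — the positive is a heavily augmented view of the
  anchor (flips, hue/contrast/brightness/saturation jitter, gaussian
  noise, specular-highlight grafting) and the negative is a different
  source image; no labels consulted.

Triplets are mined uniformly at random over the valid choices; no
hard-negative mining is performed.  Anchor and positive must be
distinct samples in the labelled regimes (a duplicate pair carries zero
gradient signal).

## Encoder

A stack of 3×3 convolution blocks (stride 1, 2×2 average pooling after
each block), global average pooling of the final feature map, and a
single affine layer into the 64-dimensional embedding.  Two presets:

* `"small"` — three plain blocks (8, 16, 32 channels).  The desk-scale
  default: it runs the full study on one CPU in minutes and is what the
  test-suite and the acceptance script use.
* `"deep"` — four residual stages (16, 32, 64, 128 channels), each two
  3×3 convolutions plus a 1×1 projection skip, in the spirit of an
  18-layer residual backbone.  No batch normalisation is used: at
  triplet batch sizes of a few dozen the extra statefulness buys little
  and inference-time determinism is simpler without it.

Forward and backward passes are NHWC float32 NumPy (im2col + GEMM), so
everything runs at BLAS speed; gradients were verified against central
finite differences.  Optimisation is Adam.  Defaults: learning rate
1e-4 for production-scale runs; the desk-scale study uses 1e-2, chosen
once by a convergence check at that scale.  Epochs consist of 100
freshly mined triplets; 25 % of the training material is held back, and
early stopping monitors the triplet loss on a fixed validation triplet
set (patience 10 by default).  The returned parameters are those of the
best validation epoch, not the last.

## Classifier heads

Three discrimination hypotheses over the latent space:

* `one_nn` — nearest neighbour; the training embeddings are stored
  verbatim as the latent-space population.  Exact distance ties break
  to the lowest training-sample index.
* `centroid` — "smallest average distance".  This phrase admits two
  readings; the default is nearest class-mean under l2 (ties to the
  lowest class index), and `params={"rule": "mean_distance"}` selects
  the smallest mean distance to the class members instead.
* `svm_rbf` — scikit-learn SVC with RBF kernel fitted on the training
  embeddings.  Defaults C = 1 and the variance-scaled kernel width
  (`gamma="scale"`); embeddings are not standardised first, because
  their scale is meaningful relative to the margin.

The variance diagnostic reports intra-class variance (mean squared l2
deviation from the class mean, summed over dimensions) and inter-class
variance (mean squared deviation of class means from their grand mean),
normalised so inter = 1.  Only ratios are interpretable; a total- vs
per-dimension convention therefore does not matter and total squared
deviation is used.  A zero raw inter-class variance raises an error
rather than silently dividing by zero.

## Evaluation protocol

Splits are drawn at the polyp-specimen level, so train and test never
share a specimen; with one image per polyp this is structural.  Default
protocol: 100 random splits, 75 % train, class-balanced test side
(every class contributes the smallest per-class test allocation; the
excess of larger classes returns to training), identical split
sequences across compared configurations under the same seed.

Per-class precision, recall, F1 and accuracy follow one-vs-rest
counting; macro values are unweighted class means, computed in exact
rational arithmetic so that the identity "accuracy = macro recall on a
balanced test set" holds bit-exactly.  F1 is averaged per repeat (the
mean F1 is not the F1 of the mean precision/recall).  Confidence
intervals are symmetric mean ± 1.6449·sd (90 %, normal approximation
over repeats, sd with n−1); percentile intervals are available.  t-SNE
projections are for inspection only and never feed metrics.

## Augmentation and specular highlights

Jitter semantics: contrast scales deviation from the image mean,
brightness is a multiplicative gain, hue shifts wrap on the hue circle,
saturation is a multiplicative HSV factor.  Default factor ranges
[0.7, 1.3] and hue ± 0.05 — the source protocol says "heavy" without
numbers, so the ranges are config-exposed.  Composition order is fixed:
flip → jitter → noise → graft.  Identity parameters reproduce the input
bit-exactly (the HSV round-trip is skipped entirely in that case).

The highlight detector marks pixels that are simultaneously very bright
(HSV value ≥ 0.9) and nearly colourless (saturation ≤ 0.3) — the
signature of sensor saturation on wet mucosa — with optional
morphological dilation.  Grafting hard-replaces pixels under the mask
(real specular highlights saturate the sensor; no alpha blending),
which also gives the strongest testable contract: pixels outside the
returned composite mask are bit-identical to the input.

## Video condensation

Consecutive frames are compared by ORB keypoint matching
(scikit-image, 500 keypoints, cross-checked matches accepted at
Hamming distance ≤ 0.20 of the descriptor bits); the score is accepted
matches over the keypoints of the sparser frame.  A score below 0.15
starts a new scene.  Frames without any keypoints score 0 and are
flagged.  Per scene the keyframe is the frame with the highest variance
of the Laplacian (sharpness; ties to the earliest frame).  The
matching-acceptance threshold was set where within-scene and
across-scene scores of the synthetic videos separate by a wide margin
(≥ 0.48 vs ≤ 0.09); both knobs are exposed.

## Synthetic data: what it emulates, what it does not

The generators provide ground-truthed stand-ins for data that cannot
ship with a package:

* **Polyp set** — two classes that differ *only* by surface texture:
  dark/white spots on homogeneous mucosa versus oval/tubular/branched
  white ridge structures.  Base colour, smooth illumination, specular
  highlights (saturated core + sub-threshold fringe, core recorded as
  ground truth) and sensor noise (σ = 0.05) are drawn identically for
  both classes, so `pattern_contrast = 0` makes the classes
  statistically indistinguishable and recovery accuracy falls to
  chance.  Per-specimen appearance variability (colour, illumination,
  pattern orientation/frequency) emulates inter-patient variation.
  Exactly one image per synthetic polyp is generated, making
  specimen-disjoint splitting structural.
* **Texture corpus** — class-specific oriented waveforms; a configured
  fraction of images blends a second class's texture and carries both
  labels, exercising the class-disjoint negative rule.
* **Videos** — scenes of near-duplicate frames (sub-pixel jitter, per-
  frame gaussian blur); the planted sharp frame is unblurred while all
  others receive blur σ > 0, so it is strictly the sharpest.

What the synthetic data does **not** capture: narrow-band-imaging
colour physics, vessel patterns, 3-D shape and shading, camera motion
blur, fluid/debris occlusion, and class boundaries that are genuinely
ambiguous to experts.  Passing tests therefore demonstrate that the
pipeline's machinery — mining, loss, optimisation, heads, splitting,
metrics — behaves correctly and can recover a planted texture signal;
they say nothing about clinical performance on real endoscopy data.

## Desk-scale study conditions

The canned study (`endofew.experiments.run_synthetic_study`, also used
by `scripts/acceptance.py`) runs at sizes chosen for a single CPU: 40
polyps per class at 32 px, pattern contrast 0.8, the `"small"` encoder
with 64-d embeddings, 20 self-supervised pretraining epochs and up to
25 fine-tuning epochs (patience 8) of 100 triplets, Adam at lr 1e-2,
and 20 shared splits.  Fine-tuning is repeated per split on the train
side only.  Depending on the seed the self-supervised encoder alone may
already separate the planted classes (the fine-tuning gain is then
zero); under the fixed study conditions of the test suite the
fine-tuned SVM exceeds 0.90 mean accuracy and improves on the frozen
pretrained encoder.

## Numerical and degenerate-case choices

* Distance gradients use a 1e-12 floor to stay defined at coincident
  embeddings; the loss itself is exact.
* Bilinear resampling for both down- and up-scaling; preprocessing is
  idempotent at the target size up to round-off.
* Bounding boxes are 0-based, half-open, and are consumed (from an
  external detector or the generator), never computed.
* Non-finite training or validation loss raises immediately with the
  epoch index.
* Known limitations: no GPU path; `AvgPool2` requires even spatial
  dimensions (input side lengths divisible by 2^blocks); multilabel
  samples cannot be used for specimen-level splitting (single-label
  only); the `"deep"` preset is untrained out of the box — no
  pretrained weights ship with the package.
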