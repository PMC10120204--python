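# endofew

Few-shot classification of colorectal polyp images by deep metric
learning, for researchers building computer-aided endoscopy systems on
very small labelled cohorts (often a single image per polyp specimen).

Instead of training a classifier end-to-end on scarce labels, an
encoder f: R^m → R^n (n = 64 by default) is trained on
(anchor, positive, negative) triplets with the contrastive triplet loss

```
L(x, x⁺, x⁻) = ‖f(x) − f(x⁺)‖₂ + max(0, m − ‖f(x) − f(x⁻)‖₂),   m = 20
```

so that l2 distance in the latent space reflects class-relevant
similarity (for NICE-style typing: spotted/homogeneous surface texture
versus tubular/branched white structures).  Simple heads — nearest
neighbour, nearest centroid, or an RBF-SVM fitted on the training
embeddings — then classify from a handful of embedded examples.

The package provides:

* the triplet loss, a NumPy convolutional encoder with analytic
  backprop, and pretrain/fine-tune loops with early stopping on a
  held-back validation portion;
* three triplet-mining regimes: class-supervised, multilabel texture
  (class-disjoint negatives), and self-supervised augmented views;
* endoscopy-specific augmentation, including specular-highlight
  detection and grafting;
* ORB-based video condensation (scene decomposition + sharpest frame);
* a repeated specimen-disjoint evaluation harness (class-balanced test
  sides, 90 % confidence intervals, per-class breakdowns, variance
  diagnostics, t-SNE export);
* synthetic-data generators with planted ground truth for all of the
  above, plus a `click` CLI (`endofew generate | pretrain | finetune |
  evaluate | keyframes`).

See `docs/methods.md` for the model, its assumptions and the design
choices.

## Worked example

```python
import endofew as ef
from endofew.triplets import mine_self_supervised

# 1. synthetic two-class polyp set: 20 polyps per class, one image each
spec = ef.SyntheticPolypSpec.default(20, pattern_contrast=0.8,
                                     image_size=32, seed=11)
dataset, truth = ef.generate_polyp_set(spec)

# 2. self-supervised pretraining of a small encoder (no labels used)
encoder = ef.build_encoder("small", embedding_dim=64, seed=0)
aug = ef.AugmentationSpec(noise_sigma=0.05)
miner = lambda samples, n, rng: mine_self_supervised(samples, aug, n, rng)
cfg = ef.TrainConfig(epochs_max=12, triplets_per_epoch=100,
                     learning_rate=1e-2, seed=1)
encoder, history = ef.pretrain(encoder, dataset.samples, miner, cfg)

# 3. repeated specimen-disjoint evaluation, SVM head on the embeddings
split_spec = ef.SplitSpec(train_fraction=0.75, n_repeats=10, seed=42)
report = ef.run_experiment(dataset, encoder, "svm_rbf", split_spec)
```

Output:

```
val triplet loss: 19.79 -> 17.24
accuracy: 96.00 (± 8.49)
F1:       95.96 (± 8.58)
intra-class variances (inter normalised to 1): {'spotted': 0.29, 'tubular': 0.51}
```

Reading the numbers: self-supervised training pulls augmented views of
an image together and pushes different specimens toward the margin, so
the validation triplet loss falls below its starting value of about 20
(the margin itself — the value of an untrained encoder whose
embeddings all coincide).  Over 10 random specimen-disjoint 75/25
splits the SVM on the frozen embeddings recovers the planted texture
classes with 96 % mean accuracy; the ± values are 90 % confidence
half-widths over splits, deliberately wide at this cohort size.  Both
intra-class variances sit well below the inter-class variance
(normalised to 1), i.e. the classes form compact, separated clusters.
Fine-tuning with class-supervised triplets
(`ef.run_experiment(..., fine_tune=True, train_cfg=..., aug=...)`)
tightens the clusters further and is compared against the frozen
encoder on identical splits.

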