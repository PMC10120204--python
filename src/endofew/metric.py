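"""Contrastive triplet loss and the pretrain / fine-tune training loops.

The loss drives the anchor-positive distance to zero while pushing the
anchor-negative distance out to an absolute margin ``m``::

    L(x, x+, x-) = D(f(x), f(x+)) + max(0, m - D(f(x), f(x-)))

with ``D`` the l2 norm by default (cosine distance available) and
``m = 20``.  The margin caps the reward for ever-larger negative
distances and thereby prevents the encoder from degenerating into a
norm-inflation solution.  The three triplet branches share weights: one
model is applied three times.

Training is plain mini-batch Adam over randomly mined triplets with
early stopping on a held-back validation portion; the returned model
carries the parameters of the best validation epoch, not the last one.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .augment import AugmentationSpec, apply_augmentation
from .data import Dataset, ImageSample
from .errors import SplitError, TrainingError, ValidationError
from .nn import Adam, EmbeddingModel
from .triplets import Triplet, mine_supervised


@dataclass
class TripletLossConfig:
    margin: float = 20.0
    metric: str = "l2"  # l2 | cosine

    def __post_init__(self):
        if self.margin < 0:
            raise ValidationError("margin must be >= 0")
        if self.metric not in ("l2", "cosine"):
            raise ValidationError(f"unknown metric {self.metric!r}")


@dataclass
class TrainConfig:
    epochs_max: int = 100
    triplets_per_epoch: int = 100
    validation_fraction: float = 0.25
    early_stop_patience: int = 10
    learning_rate: float = 1e-4
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValidationError("validation_fraction must be in [0, 1)")
        if self.early_stop_patience < 1:
            raise ValidationError("early_stop_patience must be >= 1")
        if self.epochs_max < 1 or self.triplets_per_epoch < 1:
            raise ValidationError("epochs_max and triplets_per_epoch must be >= 1")


# ------------------------------------------------------------------ loss

def _pairwise_distance(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    if metric == "l2":
        return np.linalg.norm(a - b, axis=-1)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    denom = np.maximum(na * nb, 1e-12)
    return 1.0 - (a * b).sum(axis=-1) / denom


def triplet_loss(z_anchor: np.ndarray, z_positive: np.ndarray,
                 z_negative: np.ndarray,
                 cfg: TripletLossConfig | None = None) -> float:
    """Scalar triplet loss D(za, zp) + max(0, m - D(za, zn))."""
    cfg = cfg or TripletLossConfig()
    za = np.asarray(z_anchor, dtype=np.float64)
    zp = np.asarray(z_positive, dtype=np.float64)
    zn = np.asarray(z_negative, dtype=np.float64)
    if not za.shape == zp.shape == zn.shape:
        raise ValidationError(
            f"embedding shape mismatch: {za.shape}, {zp.shape}, {zn.shape}")
    dp = _pairwise_distance(za, zp, cfg.metric)
    dn = _pairwise_distance(za, zn, cfg.metric)
    return float(np.mean(dp + np.maximum(0.0, cfg.margin - dn)))


def triplet_loss_batch(za: np.ndarray, zp: np.ndarray, zn: np.ndarray,
                       cfg: TripletLossConfig
                       ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Mean loss over a (T, d) batch plus gradients w.r.t. all embeddings."""
    T = za.shape[0]
    eps = 1e-12
    if cfg.metric == "l2":
        diff_p = za - zp
        diff_n = za - zn
        dp = np.linalg.norm(diff_p, axis=1)
        dn = np.linalg.norm(diff_n, axis=1)
        active = (dn < cfg.margin).astype(np.float64)
        loss = float(np.mean(dp + np.maximum(0.0, cfg.margin - dn)))
        gp = diff_p / np.maximum(dp, eps)[:, None]          # d dp / d za
        gn = diff_n / np.maximum(dn, eps)[:, None]          # d dn / d za
        dza = (gp - active[:, None] * gn) / T
        dzp = -gp / T
        dzn = active[:, None] * gn / T
        return loss, dza, dzp, dzn
    # cosine distance: D = 1 - <a,b> / (|a||b|)
    def cos_grads(a, b):
        na = np.maximum(np.linalg.norm(a, axis=1), eps)
        nb = np.maximum(np.linalg.norm(b, axis=1), eps)
        dot = (a * b).sum(axis=1)
        c = dot / (na * nb)
        da = -(b / (na * nb)[:, None] - (c / na ** 2)[:, None] * a)
        db = -(a / (na * nb)[:, None] - (c / nb ** 2)[:, None] * b)
        return 1.0 - c, da, db
    dp, dpa, dpp = cos_grads(za, zp)
    dn, dna, dnn = cos_grads(za, zn)
    active = (dn < cfg.margin).astype(np.float64)
    loss = float(np.mean(dp + np.maximum(0.0, cfg.margin - dn)))
    dza = (dpa - active[:, None] * dna) / T
    dzp = dpp / T
    dzn = active[:, None] * dnn / T
    return loss, dza, dzp, dzn


# ------------------------------------------------------------- embedding

def embed(model: EmbeddingModel,
          images: Sequence[ImageSample] | np.ndarray,
          batch_size: int = 64) -> np.ndarray:
    """Embed a list of samples (or an (N,H,W,3) array) row by row."""
    if isinstance(images, np.ndarray):
        x = images
    else:
        x = np.stack([s.pixels for s in images])
    out = [model.embed_batch(x[i:i + batch_size])
           for i in range(0, len(x), batch_size)]
    return np.concatenate(out, axis=0)


# ------------------------------------------------------------- training

def _triplet_arrays(triplets: Sequence[Triplet]) -> np.ndarray:
    """Stack as one (3T, H, W, 3) batch: anchors, positives, negatives."""
    xs = ([t.anchor.pixels for t in triplets]
          + [t.positive.pixels for t in triplets]
          + [t.negative.pixels for t in triplets])
    return np.stack(xs)


def _eval_loss(model: EmbeddingModel, triplets: Sequence[Triplet],
               loss_cfg: TripletLossConfig, batch_size: int) -> float:
    T = len(triplets)
    z = embed(model, _triplet_arrays(triplets), batch_size=3 * batch_size)
    return triplet_loss(z[:T], z[T:2 * T], z[2 * T:], loss_cfg)


def _train_epoch(model: EmbeddingModel, triplets: Sequence[Triplet],
                 loss_cfg: TripletLossConfig, opt: Adam,
                 batch_size: int) -> float:
    losses = []
    for start in range(0, len(triplets), batch_size):
        chunk = triplets[start:start + batch_size]
        T = len(chunk)
        x = _triplet_arrays(chunk)
        z = model.net.forward(x.astype(np.float32))
        loss, dza, dzp, dzn = triplet_loss_batch(
            z[:T].astype(np.float64), z[T:2 * T].astype(np.float64),
            z[2 * T:].astype(np.float64), loss_cfg)
        if not np.isfinite(loss):
            raise TrainingError("non-finite training loss")
        dz = np.concatenate([dza, dzp, dzn]).astype(np.float32)
        model.net.backward(dz)
        opt.step(model.net.grads())
        losses.append(loss)
    return float(np.mean(losses))


def _train_loop(model: EmbeddingModel,
                make_train_triplets: Callable[[np.random.Generator], list[Triplet]],
                val_triplets: Sequence[Triplet],
                cfg: TrainConfig,
                loss_cfg: TripletLossConfig) -> tuple[EmbeddingModel, dict]:
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.net.params(), lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"train": [], "val": []}
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0
    for epoch in range(cfg.epochs_max):
        triplets = make_train_triplets(rng)
        try:
            train_loss = _train_epoch(model, triplets, loss_cfg, opt,
                                      cfg.batch_size)
        except TrainingError as exc:
            raise TrainingError(f"epoch {epoch}: {exc}") from exc
        val_loss = _eval_loss(model, val_triplets, loss_cfg, cfg.batch_size)
        if not np.isfinite(val_loss):
            raise TrainingError(f"epoch {epoch}: non-finite validation loss")
        history["train"].append(train_loss)
        history["val"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    model.set_weights(best_weights)
    return model, history


def pretrain(model: EmbeddingModel, corpus: Sequence[ImageSample],
             miner: Callable[[Sequence[ImageSample], int, np.random.Generator],
                             list[Triplet]],
             cfg: TrainConfig,
             loss_cfg: TripletLossConfig | None = None
             ) -> tuple[EmbeddingModel, dict]:
    """Train on triplets mined from ``corpus`` by ``miner``.

    ``validation_fraction`` of the corpus is held back; a fixed triplet
    set mined from it monitors validation loss for early stopping.  The
    returned model carries the best-validation weights.
    """
    loss_cfg = loss_cfg or TripletLossConfig()
    corpus = list(corpus)
    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.validation_fraction * len(corpus)))
    perm = rng.permutation(len(corpus))
    if 0 < n_val < len(corpus):
        val_samples = [corpus[i] for i in perm[:n_val]]
        train_samples = [corpus[i] for i in perm[n_val:]]
    else:
        val_samples = train_samples = corpus
    val_triplets = miner(val_samples, cfg.triplets_per_epoch,
                         np.random.default_rng(rng.integers(2 ** 31)))
    return _train_loop(
        model,
        lambda r: miner(train_samples, cfg.triplets_per_epoch, r),
        val_triplets, cfg, loss_cfg)


def _stratified_split(dataset: Dataset, validation_fraction: float,
                      rng: np.random.Generator
                      ) -> tuple[list[ImageSample], list[ImageSample]]:
    """Per-class split guaranteeing every class appears on both sides."""
    by_class: dict[str, list[ImageSample]] = {}
    for s in dataset.labeled():
        by_class.setdefault(s.label, []).append(s)
    if len(by_class) < 2:
        raise SplitError("fine-tuning needs >= 2 labelled classes")
    train: list[ImageSample] = []
    val: list[ImageSample] = []
    for cls in sorted(by_class):
        members = by_class[cls]
        if len(members) < 2:
            raise SplitError(
                f"class {cls!r} has {len(members)} sample(s); cannot appear "
                "in both the training and validation portions")
        n_val = min(len(members) - 1,
                    max(1, int(round(validation_fraction * len(members)))))
        order = rng.permutation(len(members))
        val += [members[i] for i in order[:n_val]]
        train += [members[i] for i in order[n_val:]]
    return train, val


def finetune(model: EmbeddingModel, dataset: Dataset, cfg: TrainConfig,
             aug: AugmentationSpec | None = None,
             loss_cfg: TripletLossConfig | None = None
             ) -> tuple[EmbeddingModel, dict]:
    """Fine-tune with class-affiliation triplets.

    Triplets are mined from the training portion (with the augmentation
    pipeline applied independently to each triplet image); validation
    triplets come from the held-back portion, unaugmented.
    """
    loss_cfg = loss_cfg or TripletLossConfig()
    aug = aug or AugmentationSpec()
    rng = np.random.default_rng(cfg.seed)
    train_samples, val_samples = _stratified_split(
        dataset, cfg.validation_fraction, rng)
    val_triplets = mine_supervised(
        val_samples, cfg.triplets_per_epoch,
        np.random.default_rng(rng.integers(2 ** 31)))

    def make_train(r: np.random.Generator) -> list[Triplet]:
        triplets = mine_supervised(train_samples, cfg.triplets_per_epoch, r)
        out = []
        for t in triplets:
            out.append(Triplet(
                anchor=_augmented(t.anchor, aug, r),
                positive=_augmented(t.positive, aug, r),
                negative=_augmented(t.negative, aug, r),
                regime=t.regime))
        return out

    model.class_vocabulary = list(dataset.class_vocabulary)
    return _train_loop(model, make_train, val_triplets, cfg, loss_cfg)


def _augmented(sample: ImageSample, aug: AugmentationSpec,
               rng: np.random.Generator) -> ImageSample:
    return ImageSample(pixels=apply_augmentation(sample.pixels, aug, rng),
                       label=sample.label, polyp_id=sample.polyp_id,
                       source=sample.source)
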