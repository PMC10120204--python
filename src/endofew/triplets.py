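"""Triplet construction under the three mining regimes.

Triplets (anchor, positive, negative) are mined uniformly at random over
the valid choices — no hard-negative mining.  Regimes:

* ``supervised`` — positive shares the anchor's class, negative belongs
  to a different class (fine-tuning on labelled polyp images);
* ``multilabel`` — for corpora whose images carry label *sets*: the
  positive shares at least one label with the anchor, the negative is
  completely class-disjoint from it (texture-corpus pretraining);
* ``self_supervised`` — the positive is an augmented view of the anchor
  and the negative is a different source image; labels are never
  consulted.
"""

from __future__ import annotations

from dataclasses import dataclass
from dataclasses import replace as dc_replace
from typing import Sequence

import numpy as np

from .augment import AugmentationSpec, apply_augmentation
from .data import Dataset, ImageSample
from .errors import MiningError


@dataclass
class Triplet:
    anchor: ImageSample
    positive: ImageSample
    negative: ImageSample
    regime: str  # supervised | multilabel | self_supervised


def _class_index(samples: Sequence[ImageSample]) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        for lab in s.labels:
            idx.setdefault(lab, []).append(i)
    return idx


def mine_supervised(dataset: Dataset | Sequence[ImageSample], n_triplets: int,
                    rng: np.random.Generator) -> list[Triplet]:
    """Class-affiliation triplets, uniform over valid (anchor-class,
    negative-class) ordered pairs; anchor and positive are distinct samples."""
    samples = dataset.samples if isinstance(dataset, Dataset) else list(dataset)
    samples = [s for s in samples if s.label is not None]
    by_class = _class_index(samples)
    anchor_classes = [c for c, ids in by_class.items() if len(ids) >= 2]
    all_classes = sorted(by_class)
    if len(all_classes) < 2:
        raise MiningError("supervised mining needs >= 2 classes")
    if not anchor_classes:
        raise MiningError("no class has >= 2 samples to form a positive pair")
    pairs = [(a, n) for a in sorted(anchor_classes) for n in all_classes if n != a]
    out: list[Triplet] = []
    for _ in range(n_triplets):
        a_cls, n_cls = pairs[rng.integers(len(pairs))]
        ai, pi = rng.choice(by_class[a_cls], size=2, replace=False)
        ni = by_class[n_cls][rng.integers(len(by_class[n_cls]))]
        out.append(Triplet(samples[ai], samples[pi], samples[ni], "supervised"))
    return out


def mine_multilabel(corpus: Sequence[ImageSample], n_triplets: int,
                    rng: np.random.Generator) -> list[Triplet]:
    """Label-set triplets: positive shares >= 1 label with the anchor,
    negative is completely class-disjoint with it."""
    samples = [s for s in corpus if s.labels]
    if len(samples) < 3:
        raise MiningError("multilabel mining needs >= 3 labelled images")
    label_sets = [s.labels for s in samples]
    feasible = []
    partners: dict[int, tuple[list[int], list[int]]] = {}
    for i, ls in enumerate(label_sets):
        pos = [j for j, other in enumerate(label_sets)
               if j != i and ls & other]
        neg = [j for j, other in enumerate(label_sets) if not (ls & other)]
        if pos and neg:
            feasible.append(i)
            partners[i] = (pos, neg)
    if not feasible:
        raise MiningError("no anchor admits both a shared-label positive and "
                          "a class-disjoint negative")
    out: list[Triplet] = []
    for _ in range(n_triplets):
        ai = feasible[rng.integers(len(feasible))]
        pos, neg = partners[ai]
        pi = pos[rng.integers(len(pos))]
        ni = neg[rng.integers(len(neg))]
        out.append(Triplet(samples[ai], samples[pi], samples[ni], "multilabel"))
    return out


def mine_self_supervised(images: Sequence[ImageSample], aug: AugmentationSpec,
                         n_triplets: int,
                         rng: np.random.Generator) -> list[Triplet]:
    """Augmented-view triplets: positive = augment(anchor); negative is a
    different source image.  Labels are ignored entirely."""
    images = list(images)
    if len(images) < 2:
        raise MiningError("self-supervised mining needs >= 2 source images")
    out: list[Triplet] = []
    for _ in range(n_triplets):
        ai = int(rng.integers(len(images)))
        ni = int(rng.integers(len(images) - 1))
        ni = ni if ni < ai else ni + 1
        anchor = images[ai]
        positive = dc_replace(anchor,
                              pixels=apply_augmentation(anchor.pixels, aug, rng))
        out.append(Triplet(anchor, positive, images[ni], "self_supervised"))
    return out


def validate_triplet(t: Triplet) -> bool:
    """Exhaustive invariant check for a single triplet (used by tests)."""
    if t.regime == "supervised":
        return (t.anchor.label == t.positive.label
                and t.anchor.label != t.negative.label
                and t.anchor is not t.positive)
    if t.regime == "multilabel":
        return bool(t.anchor.labels & t.positive.labels) and not (
            t.anchor.labels & t.negative.labels)
    if t.regime == "self_supervised":
        return (t.anchor.pixels.shape == t.positive.pixels.shape
                and t.negative is not t.anchor)
    return False
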