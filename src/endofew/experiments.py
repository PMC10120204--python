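"""Canned end-to-end study on synthetic data.

Reproduces the structure of the full pipeline at desk scale: generate a
two-class polyp set, pretrain the encoder self-supervised on those
images (no labels consulted), then evaluate each classifier head over
repeated specimen-disjoint splits with and without per-split fine-tuning
— the fine-tuned vs not-fine-tuned contrast being the study's central
comparison.

Default study conditions: 40 polyps per class at 32 px with pattern
contrast 0.8, the "small" three-block encoder with a 64-d embedding,
margin-20 l2 triplet loss, 20 self-supervised pretraining epochs and up
to 25 fine-tuning epochs of 100 triplets each (Adam, lr 1e-2), and 20
shared splits.  One seed drives everything.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentationSpec
from .evaluate import EvalReport, SplitSpec, make_splits, run_experiment
from .metric import TrainConfig, TripletLossConfig, pretrain
from .nn import EmbeddingModel, build_encoder
from .synthetic import (SyntheticPolypSpec, generate_highlight_bank,
                        generate_polyp_set)
from .triplets import mine_self_supervised


def _derive(seed: int, tag: str) -> int:
    return int(np.random.SeedSequence(
        [seed, zlib.crc32(tag.encode())]).generate_state(1)[0] % (2 ** 31))


@dataclass
class SyntheticStudyConfig:
    seed: int = 11
    n_polyps_per_class: int = 40
    image_size: int = 32
    pattern_contrast: float = 0.8
    depth_spec: object = "small"
    embedding_dim: int = 64
    pretrain_epochs: int = 20
    finetune_epochs: int = 25
    finetune_patience: int = 8
    triplets_per_epoch: int = 100
    learning_rate: float = 1e-2
    n_repeats: int = 20
    heads: tuple[str, ...] = ("svm_rbf",)
    loss: TripletLossConfig = field(default_factory=TripletLossConfig)


@dataclass
class SyntheticStudyResult:
    dataset: object
    encoder: EmbeddingModel
    pretrain_history: dict
    reports: dict  # (head, "pretrained"|"finetuned") -> EvalReport


def run_synthetic_study(cfg: SyntheticStudyConfig | None = None
                        ) -> SyntheticStudyResult:
    cfg = cfg or SyntheticStudyConfig()
    spec = SyntheticPolypSpec.default(cfg.n_polyps_per_class,
                                      cfg.pattern_contrast,
                                      image_size=cfg.image_size,
                                      seed=_derive(cfg.seed, "polyps"))
    dataset, _ = generate_polyp_set(spec)

    bank = generate_highlight_bank(8, size_range=(4, 8),
                                   seed=_derive(cfg.seed, "bank"))
    aug_ss = AugmentationSpec(noise_sigma=0.05, graft_highlights=True,
                              highlight_bank=bank, n_highlights=1)
    aug_ft = AugmentationSpec()  # flips + photometric jitter only

    encoder = build_encoder(cfg.depth_spec, cfg.embedding_dim,
                            seed=_derive(cfg.seed, "encoder"))
    pre_cfg = TrainConfig(epochs_max=cfg.pretrain_epochs,
                          triplets_per_epoch=cfg.triplets_per_epoch,
                          early_stop_patience=cfg.pretrain_epochs,
                          learning_rate=cfg.learning_rate,
                          seed=_derive(cfg.seed, "pretrain"))
    miner = lambda samples, n, rng: mine_self_supervised(samples, aug_ss,
                                                         n, rng)
    encoder, history = pretrain(encoder, dataset.samples, miner, pre_cfg,
                                cfg.loss)

    split_spec = SplitSpec(n_repeats=cfg.n_repeats,
                           seed=_derive(cfg.seed, "splits"))
    splits = make_splits(dataset, split_spec)
    ft_cfg = TrainConfig(epochs_max=cfg.finetune_epochs,
                         triplets_per_epoch=cfg.triplets_per_epoch,
                         early_stop_patience=cfg.finetune_patience,
                         learning_rate=cfg.learning_rate,
                         seed=_derive(cfg.seed, "finetune"))
    reports = {}
    for head in cfg.heads:
        reports[(head, "pretrained")] = run_experiment(
            dataset, encoder, head, split_spec, fine_tune=False,
            loss_cfg=cfg.loss, splits=splits, with_variances=(head == cfg.heads[0]))
        reports[(head, "finetuned")] = run_experiment(
            dataset, encoder, head, split_spec, fine_tune=True,
            train_cfg=ft_cfg, aug=aug_ft, loss_cfg=cfg.loss, splits=splits,
            with_variances=False)
    return SyntheticStudyResult(dataset=dataset, encoder=encoder,
                                pretrain_history=history, reports=reports)
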