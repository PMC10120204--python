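"""Experiment configuration: one YAML file drives every pipeline stage.

A single global ``seed`` deterministically derives per-stage seeds
(:meth:`ExperimentConfig.stage_seed`), so a whole experiment is
reproducible from the config alone.  Unknown keys anywhere in the file
are rejected before anything runs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .augment import AugmentationSpec
from .errors import ConfigurationError
from .metric import TrainConfig, TripletLossConfig

PRETRAIN_REGIMES = ("dtd_style_supervised", "self_supervised", "none")


def _build(cls, raw: dict, context: str):
    try:
        return cls(**raw)
    except TypeError as exc:
        raise ConfigurationError(f"{context}: {exc}") from exc


@dataclass
class EncoderConfig:
    depth_spec: Any = "small"
    embedding_dim: int = 64

    def __post_init__(self):
        if not isinstance(self.depth_spec, str):
            self.depth_spec = tuple(int(c) for c in self.depth_spec)


@dataclass
class DataConfig:
    manifest: Optional[str] = None
    image_root: Optional[str] = None
    target_size: int = 32


@dataclass
class SyntheticConfig:
    n_polyps_per_class: int = 40
    image_size: int = 32
    pattern_contrast: float = 0.8
    highlight_density: float = 2.0
    noise_sigma: float = 0.05
    texture_classes: int = 4
    texture_images_per_class: int = 10
    multilabel_fraction: float = 0.25
    video_scenes: int = 3
    frames_per_scene: int = 10
    highlight_bank_size: int = 8


@dataclass
class SplitConfig:
    train_fraction: float = 0.75
    balanced_test: bool = True
    n_repeats: int = 20


@dataclass
class ExperimentConfig:
    seed: int = 0
    output_dir: str = "runs/default"
    pretraining_regime: str = "self_supervised"
    heads: tuple[str, ...] = ("one_nn", "centroid", "svm_rbf")
    fine_tune: bool = True
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    loss: TripletLossConfig = field(default_factory=TripletLossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    data: DataConfig = field(default_factory=DataConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    split: SplitConfig = field(default_factory=SplitConfig)

    def __post_init__(self):
        if self.pretraining_regime not in PRETRAIN_REGIMES:
            raise ConfigurationError(
                f"pretraining_regime must be one of {PRETRAIN_REGIMES}")
        self.heads = tuple(self.heads)

    @classmethod
    def from_yaml(cls, path: str | Path,
                  overrides: Optional[dict] = None) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides or {})
        known_nested = {"encoder": EncoderConfig, "loss": TripletLossConfig,
                        "train": TrainConfig, "augmentation": AugmentationSpec,
                        "data": DataConfig, "synthetic": SyntheticConfig,
                        "split": SplitConfig}
        kwargs: dict = {}
        for key, value in raw.items():
            if key in known_nested:
                if not isinstance(value, dict):
                    raise ConfigurationError(f"{key}: expected a mapping")
                for sub in ("contrast_range", "brightness_range",
                            "saturation_range"):
                    if sub in value:
                        value[sub] = tuple(value[sub])
                kwargs[key] = _build(known_nested[key], value, key)
            elif key in ("seed", "output_dir", "pretraining_regime", "heads",
                         "fine_tune"):
                kwargs[key] = value
            else:
                raise ConfigurationError(f"unknown config key {key!r}")
        return _build(cls, kwargs, "experiment")

    def stage_seed(self, tag: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        return int(np.random.SeedSequence(
            [self.seed, zlib.crc32(tag.encode())]).generate_state(1)[0]
            % (2 ** 31))

    def resolved(self) -> dict:
        out = asdict(self)
        out["augmentation"].pop("highlight_bank", None)
        return out

    def write_snapshot(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "resolved_config.json"
        with open(path, "w") as fh:
            json.dump(self.resolved(), fh, indent=1, default=str)
        return path
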