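"""Dataset model, manifest I/O and image preprocessing.

Images are RGB float arrays in [0, 1].  A manifest is a CSV with columns
``path``, ``label``, ``polyp_id`` and optionally ``x_min, y_min, width,
height`` (a 0-based, half-open bounding box in original-image pixels).
Rows without a label are kept as unlabeled samples so they can feed the
self-supervised stages; supervised operations refuse them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from .errors import ManifestError, ValidationError

#: label of a sample: a single class id, a set of class ids (multilabel
#: texture corpora) or None for unlabeled data.
Label = Union[str, frozenset, None]

BBox = tuple[int, int, int, int]  # (x_min, y_min, width, height)


@dataclass
class ImageSample:
    """One image with its class label and provenance.

    ``polyp_id`` identifies the physical specimen; datasets in
    one-image-per-polyp mode carry a distinct id per sample, which makes
    specimen-disjoint splitting structural.
    """

    pixels: np.ndarray  # H x W x 3 float in [0, 1]
    label: Label = None
    polyp_id: str = ""
    source: str = ""
    bbox: Optional[BBox] = None

    @property
    def labels(self) -> frozenset:
        """Label-set view: singleton for plain labels, empty if unlabeled."""
        if self.label is None:
            return frozenset()
        if isinstance(self.label, frozenset):
            return self.label
        return frozenset([self.label])


@dataclass
class Dataset:
    samples: list[ImageSample] = field(default_factory=list)
    class_vocabulary: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    def labeled(self) -> list[ImageSample]:
        return [s for s in self.samples if s.label is not None]

    def by_class(self) -> dict[str, list[int]]:
        """Class id -> indices of samples carrying that label."""
        out: dict[str, list[int]] = {c: [] for c in self.class_vocabulary}
        for i, s in enumerate(self.samples):
            for lab in s.labels:
                out.setdefault(lab, []).append(i)
        return out


def _load_image(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    return arr


def _validate_bbox(bbox: BBox, shape: tuple[int, ...], context: str) -> None:
    x, y, w, h = bbox
    H, W = shape[:2]
    if w <= 0 or h <= 0:
        raise ValidationError(f"{context}: degenerate bbox {bbox}")
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValidationError(
            f"{context}: bbox {bbox} outside image bounds {(H, W)}"
        )


def load_manifest(manifest_path: str | Path, image_root: str | Path) -> Dataset:
    """Load a CSV manifest into a :class:`Dataset`.

    Rows with an empty/missing ``label`` are retained as unlabeled.
    Missing image files and out-of-bounds boxes raise errors naming the
    offending row.
    """
    manifest_path = Path(manifest_path)
    image_root = Path(image_root)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    if "path" not in df.columns:
        raise ManifestError("manifest lacks required 'path' column")
    has_bbox = {"x_min", "y_min", "width", "height"}.issubset(df.columns)

    samples: list[ImageSample] = []
    for row_idx, row in df.iterrows():
        img_path = image_root / str(row["path"])
        if not img_path.exists():
            raise ManifestError(f"row {row_idx}: image not found: {img_path}")
        pixels = _load_image(img_path)
        label: Label = None
        if "label" in df.columns and not pd.isna(row["label"]):
            raw = str(row["label"])
            parts = [p for p in raw.split("|") if p]
            label = parts[0] if len(parts) == 1 else frozenset(parts)
        bbox: Optional[BBox] = None
        if has_bbox and not pd.isna(row["x_min"]):
            try:
                bbox = (
                    int(row["x_min"]),
                    int(row["y_min"]),
                    int(row["width"]),
                    int(row["height"]),
                )
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"row {row_idx}: malformed bbox") from exc
            _validate_bbox(bbox, pixels.shape, f"row {row_idx}")
        polyp_id = str(row["polyp_id"]) if "polyp_id" in df.columns else str(row_idx)
        samples.append(
            ImageSample(pixels=pixels, label=label, polyp_id=polyp_id,
                        source=str(row["path"]), bbox=bbox)
        )

    vocab = sorted({lab for s in samples for lab in s.labels})
    return Dataset(samples=samples, class_vocabulary=vocab)


def save_dataset(dataset: Dataset, out_dir: str | Path,
                 ground_truth: Optional[dict] = None) -> Path:
    """Write PNG images + manifest CSV (+ optional JSON ground-truth sidecar).

    Returns the manifest path.  ``load_manifest`` round-trips labels, ids
    and bounding boxes exactly.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(dataset.samples):
        name = f"img_{i:05d}.png"
        arr = np.clip(s.pixels * 255.0 + 0.5, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(img_dir / name)
        if s.label is None:
            label_str = ""
        elif isinstance(s.label, frozenset):
            label_str = "|".join(sorted(s.label))
        else:
            label_str = s.label
        row = {"path": f"images/{name}", "label": label_str,
               "polyp_id": s.polyp_id}
        if s.bbox is not None:
            row.update(zip(("x_min", "y_min", "width", "height"), s.bbox))
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if ground_truth is not None:
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(ground_truth, fh, indent=1)
    return manifest


def preprocess(sample: ImageSample, target_size: int = 224) -> ImageSample:
    """Crop to the polyp bounding box (if any) and resample to a square.

    Bilinear resampling for both down- and up-sampling; output values are
    clipped to [0, 1] and the bbox is consumed (set to None).
    """
    if target_size < 1:
        raise ValidationError(f"target_size must be >= 1, got {target_size}")
    pixels = sample.pixels
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 image, got {pixels.shape}")
    if sample.bbox is not None:
        _validate_bbox(sample.bbox, pixels.shape, f"sample {sample.polyp_id}")
        x, y, w, h = sample.bbox
        pixels = pixels[y:y + h, x:x + w]
    if pixels.shape[:2] != (target_size, target_size):
        pixels = resize(pixels, (target_size, target_size), order=1,
                        mode="reflect", anti_aliasing=False,
                        preserve_range=True)
    pixels = np.clip(pixels, 0.0, 1.0)
    return replace(sample, pixels=pixels, bbox=None)


def preprocess_all(samples: Sequence[ImageSample],
                   target_size: int = 224) -> list[ImageSample]:
    return [preprocess(s, target_size) for s in samples]
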