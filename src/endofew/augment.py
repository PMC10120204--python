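"""Endoscopy-flavoured image augmentation.

The augmentation set mirrors what is useful on endoscopic frames: random
flips along both image axes, photometric jitter of hue / contrast /
brightness / saturation, additive gaussian pixel noise, and — specific to
this domain — detection and grafting of specular highlights, the
saturated reflections that wet mucosa produces under the endoscope light.

All operators are pure given their RNG, keep values in [0, 1], and
compose in the fixed order flip -> jitter -> noise -> graft
(:func:`apply_augmentation`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

from .errors import ConfigurationError, ValidationError


@dataclass
class HighlightMask:
    """A specular highlight cut out of some image: binary footprint + pixels."""

    mask: np.ndarray   # H' x W' bool
    patch: np.ndarray  # H' x W' x 3 float in [0, 1]

    def __post_init__(self):
        if self.mask.shape != self.patch.shape[:2]:
            raise ValidationError("highlight mask/patch shape mismatch")
        if not self.mask.any():
            raise ValidationError("highlight mask is empty")


@dataclass
class AugmentationSpec:
    """Parameters of the augmentation pipeline.

    Jitter factors are multiplicative (1.0 = identity) and drawn uniformly
    from their ranges; the hue shift is a fraction of the hue circle drawn
    from [-hue_delta, +hue_delta].  ``noise_sigma = 0`` disables noise and
    an empty ``highlight_bank`` (or ``graft_highlights=False``) disables
    grafting.
    """

    flip_axes: tuple[str, ...] = ("horizontal", "vertical")
    hue_delta: float = 0.05
    contrast_range: tuple[float, float] = (0.7, 1.3)
    brightness_range: tuple[float, float] = (0.7, 1.3)
    saturation_range: tuple[float, float] = (0.7, 1.3)
    noise_sigma: float = 0.0
    graft_highlights: bool = False
    highlight_bank: list[HighlightMask] = field(default_factory=list)
    n_highlights: int = 2

    def __post_init__(self):
        for name in ("contrast_range", "brightness_range", "saturation_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name}: inverted bounds ({lo}, {hi})")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.hue_delta < 0:
            raise ValidationError("hue_delta must be >= 0")
        unknown = set(self.flip_axes) - {"horizontal", "vertical"}
        if unknown:
            raise ValidationError(f"unknown flip axes: {unknown}")

    @classmethod
    def identity(cls) -> "AugmentationSpec":
        return cls(flip_axes=(), hue_delta=0.0, contrast_range=(1.0, 1.0),
                   brightness_range=(1.0, 1.0), saturation_range=(1.0, 1.0),
                   noise_sigma=0.0, graft_highlights=False)


def random_flip(image: np.ndarray, rng: np.random.Generator,
                axes: Sequence[str] = ("horizontal", "vertical")) -> np.ndarray:
    """Flip along each listed axis independently with probability 1/2."""
    out = image
    for axis_name, axis in (("vertical", 0), ("horizontal", 1)):
        if axis_name in axes and rng.random() < 0.5:
            out = np.flip(out, axis=axis)
    return np.ascontiguousarray(out)


def photometric_jitter(image: np.ndarray, spec: AugmentationSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """Random hue / contrast / brightness / saturation modification.

    Contrast scales deviation from the image mean, brightness is a plain
    multiplicative gain, hue shifts wrap circularly and saturation is a
    multiplicative factor in HSV.  Degenerate identity ranges leave the
    image bit-identical (the HSV round-trip is skipped entirely).
    """
    c = rng.uniform(*spec.contrast_range)
    b = rng.uniform(*spec.brightness_range)
    s = rng.uniform(*spec.saturation_range)
    h = rng.uniform(-spec.hue_delta, spec.hue_delta) if spec.hue_delta else 0.0

    out = image
    if c != 1.0:
        mean = out.mean()
        out = mean + c * (out - mean)
    if b != 1.0:
        out = out * b
    if h != 0.0 or s != 1.0:
        hsv = rgb2hsv(np.clip(out, 0.0, 1.0))
        hsv[..., 0] = (hsv[..., 0] + h) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * s, 0.0, 1.0)
        out = hsv2rgb(hsv)
    if out is image:
        return image
    return np.clip(out, 0.0, 1.0)


def add_gaussian_noise(image: np.ndarray, sigma: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Additive i.i.d. gaussian pixel noise, clipped to [0, 1]."""
    if sigma < 0:
        raise ValidationError("sigma must be >= 0")
    if sigma == 0:
        return image
    return np.clip(image + rng.normal(0.0, sigma, size=image.shape), 0.0, 1.0)


def _saturation(image: np.ndarray) -> np.ndarray:
    """HSV-style saturation: (max - min) / max, zero for black pixels."""
    mx = image.max(axis=2)
    mn = image.min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(mx > 0, (mx - mn) / np.where(mx > 0, mx, 1.0), 0.0)
    return sat


def detect_specular_highlights(image: np.ndarray,
                               brightness_threshold: float = 0.9,
                               saturation_threshold: float = 0.3,
                               dilation_radius: int = 1) -> Optional[HighlightMask]:
    """Threshold-based specular highlight detector.

    Marks pixels that are simultaneously very bright (HSV value above
    ``brightness_threshold``) and nearly colorless (saturation below
    ``saturation_threshold``) — the signature of sensor-saturating
    reflections — then dilates the footprint by ``dilation_radius``.
    Returns None when no highlight is found.
    """
    for name, t in (("brightness_threshold", brightness_threshold),
                    ("saturation_threshold", saturation_threshold)):
        if not 0.0 <= t <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {t}")
    value = image.max(axis=2)
    mask = (value >= brightness_threshold) & (_saturation(image) <= saturation_threshold)
    if dilation_radius > 0:
        yy, xx = np.mgrid[-dilation_radius:dilation_radius + 1,
                          -dilation_radius:dilation_radius + 1]
        selem = (yy ** 2 + xx ** 2) <= dilation_radius ** 2
        mask = ndimage.binary_dilation(mask, structure=selem)
    if not mask.any():
        return None
    return HighlightMask(mask=mask, patch=image.copy())


def graft_highlights(image: np.ndarray, bank: Sequence[HighlightMask],
                     n_highlights: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Paste ``n_highlights`` bank entries at random positions.

    Pixels under the composite mask are hard-replaced by patch values
    (specular highlights saturate the sensor, so no alpha blending);
    pixels outside the returned mask are bit-identical to the input.
    """
    if n_highlights < 0:
        raise ValidationError("n_highlights must be >= 0")
    if n_highlights > 0 and not bank:
        raise ConfigurationError("empty highlight bank with n_highlights > 0")
    H, W = image.shape[:2]
    out = image.copy()
    composite = np.zeros((H, W), dtype=bool)
    for _ in range(n_highlights):
        entry = bank[rng.integers(len(bank))]
        h, w = entry.mask.shape
        if h > H or w > W:
            raise ValidationError("highlight patch larger than target image")
        y = int(rng.integers(0, H - h + 1))
        x = int(rng.integers(0, W - w + 1))
        region = out[y:y + h, x:x + w]
        region[entry.mask] = entry.patch[entry.mask]
        composite[y:y + h, x:x + w] |= entry.mask
    return out, composite


def apply_augmentation(image: np.ndarray, spec: AugmentationSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """Full pipeline in fixed order: flip -> jitter -> noise -> graft."""
    out = random_flip(image, rng, spec.flip_axes) if spec.flip_axes else image
    out = photometric_jitter(out, spec, rng)
    out = add_gaussian_noise(out, spec.noise_sigma, rng)
    if spec.graft_highlights and spec.highlight_bank:
        out, _ = graft_highlights(out, spec.highlight_bank,
                                  spec.n_highlights, rng)
    return out


def save_highlight_bank(bank: Sequence[HighlightMask], out_dir: str | Path) -> Path:
    """Serialize a bank as paired PNGs (mask, patch) with a JSON index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for i, e in enumerate(bank):
        mask_name, patch_name = f"mask_{i:04d}.png", f"patch_{i:04d}.png"
        Image.fromarray((e.mask * 255).astype(np.uint8)).save(out_dir / mask_name)
        Image.fromarray(
            np.clip(e.patch * 255.0 + 0.5, 0, 255).astype(np.uint8)
        ).save(out_dir / patch_name)
        index.append({"mask": mask_name, "patch": patch_name})
    index_path = out_dir / "index.json"
    with open(index_path, "w") as fh:
        json.dump(index, fh)
    return index_path


def load_highlight_bank(index_path: str | Path) -> list[HighlightMask]:
    index_path = Path(index_path)
    with open(index_path) as fh:
        index = json.load(fh)
    bank = []
    for entry in index:
        mask = np.asarray(Image.open(index_path.parent / entry["mask"])) > 127
        patch = np.asarray(
            Image.open(index_path.parent / entry["patch"]).convert("RGB"),
            dtype=np.float64) / 255.0
        bank.append(HighlightMask(mask=mask, patch=patch))
    return bank
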