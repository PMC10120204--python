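"""Synthetic fixtures with known ground truth.

Real narrow-band-imaging polyp data cannot ship with a package, so every
stage of the pipeline is exercised on procedurally generated imagery:

* a two-class "polyp" set whose classes differ *only* by surface texture —
  dark/white spots on a homogeneous mucosa (hyperplastic-like) versus
  oval/tubular white ridge structures (adenoma-like) — with shared base
  color statistics, per-specimen appearance variability, superimposed
  specular highlights and sensor noise;
* a multilabel texture corpus standing in for a describable-textures
  pretraining set;
* scene-structured videos of near-duplicate frames with varying blur, for
  the keyframe-condensation stage;
* banks of specular-highlight patches for the grafting augmentation.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .augment import HighlightMask
from .data import Dataset, ImageSample
from .errors import ConfigurationError

#: default per-class texture parameters; both classes share base color
#: statistics so that only the surface pattern is discriminative.
DEFAULT_CLASS_PARAMS = {
    "spotted": {"spot_density": 0.04, "tubule_frequency": 0.0,
                "pattern_contrast": 0.8},
    "tubular": {"spot_density": 0.0, "tubule_frequency": 9.0,
                "pattern_contrast": 0.8},
}


@dataclass
class SyntheticPolypSpec:
    n_polyps_per_class: int = 20
    image_size: int = 224
    class_texture_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_PARAMS.items()})
    highlight_density: float = 2.0   # expected highlights per image (Poisson)
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_polyps_per_class < 1:
            raise ConfigurationError("n_polyps_per_class must be >= 1")
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        if self.highlight_density < 0 or self.noise_sigma < 0:
            raise ConfigurationError("densities/sigmas must be >= 0")

    @classmethod
    def default(cls, n_polyps_per_class: int, pattern_contrast: float = 0.8,
                image_size: int = 224, seed: int = 0, **kw) -> "SyntheticPolypSpec":
        params = {k: dict(v) for k, v in DEFAULT_CLASS_PARAMS.items()}
        for v in params.values():
            v["pattern_contrast"] = pattern_contrast
        return cls(n_polyps_per_class=n_polyps_per_class, image_size=image_size,
                   class_texture_params=params, seed=seed, **kw)


@dataclass
class SyntheticVideoSpec:
    n_scenes: int = 3
    frames_per_scene: int = 10
    sharp_frame_index_per_scene: Optional[list[int]] = None  # None -> random
    frame_size: int = 128
    inter_scene_translation: float = 8.0
    blur_sigma_range: tuple[float, float] = (0.8, 2.5)
    seed: int = 0

    def __post_init__(self):
        if self.n_scenes < 1:
            raise ConfigurationError("n_scenes must be >= 1")
        if self.frames_per_scene < 1:
            raise ConfigurationError("frames_per_scene must be >= 1")
        if self.sharp_frame_index_per_scene is not None:
            if len(self.sharp_frame_index_per_scene) != self.n_scenes:
                raise ConfigurationError("one sharp index per scene required")
            if any(not 0 <= i < self.frames_per_scene
                   for i in self.sharp_frame_index_per_scene):
                raise ConfigurationError("sharp frame index out of scene range")
        lo, hi = self.blur_sigma_range
        if not 0 < lo <= hi:
            raise ConfigurationError(
                "blur_sigma_range must satisfy 0 < lo <= hi (the planted "
                "sharp frame is unblurred and must be strictly sharpest)")


@dataclass
class GroundTruth:
    """What the generators planted, for downstream recovery checks."""

    class_labels: Optional[list[str]] = None
    highlight_masks: Optional[list[np.ndarray]] = None
    scene_boundaries: Optional[list[int]] = None
    planted_keyframe_indices: Optional[list[int]] = None

    def to_jsonable(self) -> dict:
        out: dict = {}
        if self.class_labels is not None:
            out["class_labels"] = list(self.class_labels)
        if self.highlight_masks is not None:
            out["highlight_masks"] = [m.astype(int).tolist()
                                      for m in self.highlight_masks]
        if self.scene_boundaries is not None:
            out["scene_boundaries"] = list(self.scene_boundaries)
        if self.planted_keyframe_indices is not None:
            out["planted_keyframe_indices"] = list(self.planted_keyframe_indices)
        return out


# ---------------------------------------------------------------- helpers

def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Zero-mean, unit-std smooth random field."""
    f = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)
    std = f.std()
    return f / std if std > 0 else f


def _hsv_to_rgb_scalar(h: float, s: float, v: float) -> np.ndarray:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb)


def _render_highlight_blob(rng: np.random.Generator,
                           size: int) -> tuple[np.ndarray, np.ndarray]:
    """Soft elliptical blob in [0,1] plus its saturated core mask."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    ry = size * rng.uniform(0.28, 0.42)
    rx = size * rng.uniform(0.28, 0.42)
    theta = rng.uniform(0, np.pi)
    y, x = yy - cy, xx - cx
    u = (x * np.cos(theta) + y * np.sin(theta)) / rx
    w = (-x * np.sin(theta) + y * np.cos(theta)) / ry
    r2 = u ** 2 + w ** 2
    blob = np.exp(-1.8 * r2)
    core = blob > 0.55
    if not core.any():
        core[size // 2, size // 2] = True
    return blob, core


def _paste_highlight(img: np.ndarray, rng: np.random.Generator,
                     mask_accum: np.ndarray) -> None:
    """Render one saturated highlight in place; core footprint -> mask_accum.

    The core is hard near-white (what a real sensor saturates to); a dim
    soft fringe surrounds it but stays well below typical detection
    thresholds so the recorded mask matches the detectable footprint.
    """
    H = img.shape[0]
    size = int(rng.integers(max(4, H // 24), max(6, H // 10)))
    blob, core = _render_highlight_blob(rng, size)
    y = int(rng.integers(0, H - size + 1))
    x = int(rng.integers(0, H - size + 1))
    region = img[y:y + size, x:x + size]
    fringe_alpha = np.clip(blob, 0, 1)[..., None] * 0.35
    region[:] = region * (1 - fringe_alpha) + 1.0 * fringe_alpha
    white = rng.uniform(0.95, 1.0)
    region[core] = white
    mask_accum[y:y + size, x:x + size] |= core


def _base_mucosa(rng: np.random.Generator, size: int) -> np.ndarray:
    """Pinkish mucosa with per-specimen color and smooth illumination."""
    h = (0.015 + 0.02 * rng.standard_normal()) % 1.0
    s = rng.uniform(0.35, 0.55)
    v = rng.uniform(0.5, 0.72)
    base = _hsv_to_rgb_scalar(h, s, v)
    illum = 1.0 + 0.13 * _smooth_field(rng, size, size / 8.0)
    return base[None, None, :] * illum[..., None]


def _spot_texture(rng: np.random.Generator, size: int,
                  spot_density: float) -> np.ndarray:
    """Signed field of dark/white round spots (homogeneous mucosa pattern)."""
    tex = np.zeros((size, size))
    mean_r = max(1.5, size * 0.022)
    n_spots = max(1, int(round(spot_density * size * size / (np.pi * mean_r ** 2))))
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    for _ in range(n_spots):
        cy, cx = rng.uniform(0, size, 2)
        r = mean_r * rng.uniform(0.6, 1.6)
        sign = -1.0 if rng.random() < 0.5 else 1.0
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        tex += sign * np.exp(-d2 / (2 * (r / 1.5) ** 2))
    return np.clip(tex, -1.0, 1.0)


def _ridge_texture(rng: np.random.Generator, size: int,
                   frequency: float) -> np.ndarray:
    """Oval/tubular/branched white ridge structures (adenomatous pattern)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / size
    warp = 0.08 * _smooth_field(rng, size, size / 10.0)
    theta = rng.uniform(0, np.pi)
    f = frequency * rng.uniform(0.8, 1.2)
    u1 = xx * np.cos(theta) + yy * np.sin(theta) + warp
    r1 = np.sin(2 * np.pi * f * u1 + rng.uniform(0, 2 * np.pi))
    theta2 = theta + rng.uniform(0.8, 2.3)
    u2 = xx * np.cos(theta2) + yy * np.sin(theta2) + warp
    r2 = np.sin(2 * np.pi * f * 0.8 * u2 + rng.uniform(0, 2 * np.pi))
    ridges = np.maximum(r1, 0.7 * r2)
    # soft-threshold into white tubular structures on neutral background
    return np.clip((ridges - 0.25) / 0.75, 0.0, 1.0)


def generate_polyp_set(spec: SyntheticPolypSpec) -> tuple[Dataset, GroundTruth]:
    """Two-class polyp-like image set, exactly one image per synthetic polyp.

    Class identity is carried purely by the surface pattern; base color,
    illumination, highlight and noise statistics are drawn identically for
    both classes, so ``pattern_contrast = 0`` makes the classes
    statistically indistinguishable.
    """
    master = np.random.default_rng(spec.seed)
    samples: list[ImageSample] = []
    labels: list[str] = []
    masks: list[np.ndarray] = []
    size = spec.image_size
    class_names = sorted(spec.class_texture_params)
    pid = 0
    for cname in class_names:
        params = spec.class_texture_params[cname]
        for _ in range(spec.n_polyps_per_class):
            rng = np.random.default_rng(master.integers(2 ** 31))
            img = _base_mucosa(rng, size)
            contrast = float(params.get("pattern_contrast", 0.8))
            spot_density = float(params.get("spot_density", 0.0))
            tubule_frequency = float(params.get("tubule_frequency", 0.0))
            if spot_density > 0:
                tex = _spot_texture(rng, size, spot_density)
                img += (contrast * 0.38 * tex)[..., None]
            if tubule_frequency > 0:
                tex = _ridge_texture(rng, size, tubule_frequency)
                # white structures: lift towards white, strongest in G/B
                img += (contrast * 0.42 * tex)[..., None] * np.array([0.75, 1.0, 1.0])
            img = np.clip(img, 0.0, 1.0)
            mask = np.zeros((size, size), dtype=bool)
            for _ in range(rng.poisson(spec.highlight_density)):
                _paste_highlight(img, rng, mask)
            if spec.noise_sigma > 0:
                img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
            img = np.clip(img, 0.0, 1.0)
            samples.append(ImageSample(pixels=img, label=cname,
                                       polyp_id=f"polyp_{pid:04d}",
                                       source="synthetic"))
            labels.append(cname)
            masks.append(mask)
            pid += 1
    dataset = Dataset(samples=samples, class_vocabulary=class_names)
    return dataset, GroundTruth(class_labels=labels, highlight_masks=masks)


# ------------------------------------------------------- texture corpus

def _class_texture(rng: np.random.Generator, size: int, class_idx: int,
                   n_classes: int) -> np.ndarray:
    """Deterministic texture family per class: oriented waves with
    class-specific orientation, frequency and waveform."""
    theta = np.pi * class_idx / n_classes
    f = 5.0 + 2.0 * class_idx
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / size
    u = xx * np.cos(theta) + yy * np.sin(theta)
    wave = np.sin(2 * np.pi * f * u + rng.uniform(0, 2 * np.pi))
    if class_idx % 2 == 1:
        wave = np.sign(wave)  # square grating
    if class_idx % 3 == 2:
        v = -xx * np.sin(theta) + yy * np.cos(theta)
        wave = wave * np.sin(2 * np.pi * f * v + rng.uniform(0, 2 * np.pi))
    return wave


def generate_texture_corpus(n_classes: int, n_images_per_class: int,
                            multilabel_fraction: float, seed: int,
                            image_size: int = 64) -> list[ImageSample]:
    """Multilabel texture corpus (describable-textures stand-in).

    Each image carries a non-empty label-set; a ``multilabel_fraction``
    of images blend a second class's texture and carry both labels.
    """
    if n_classes < 2:
        raise ConfigurationError("n_classes must be >= 2")
    if not 0.0 <= multilabel_fraction <= 1.0:
        raise ConfigurationError("multilabel_fraction must be in [0, 1]")
    if n_images_per_class < 1:
        raise ConfigurationError("n_images_per_class must be >= 1")
    master = np.random.default_rng(seed)
    total = n_classes * n_images_per_class
    n_multi = int(round(multilabel_fraction * total))
    multi_slots = set(master.choice(total, size=n_multi, replace=False).tolist())

    samples: list[ImageSample] = []
    idx = 0
    for c in range(n_classes):
        for _ in range(n_images_per_class):
            rng = np.random.default_rng(master.integers(2 ** 31))
            tex = _class_texture(rng, image_size, c, n_classes)
            label_set = {f"tex{c:02d}"}
            if idx in multi_slots:
                other = int(rng.integers(n_classes - 1))
                other = other if other < c else other + 1
                tex = 0.5 * tex + 0.5 * _class_texture(rng, image_size,
                                                       other, n_classes)
                label_set.add(f"tex{other:02d}")
            gray = 0.5 + 0.3 * tex
            img = np.repeat(gray[..., None], 3, axis=2)
            img += rng.normal(0.0, 0.02, img.shape)
            img = np.clip(img, 0.0, 1.0)
            samples.append(ImageSample(
                pixels=img,
                label=frozenset(label_set) if len(label_set) > 1
                else next(iter(label_set)),
                polyp_id=f"tex_{idx:05d}", source="synthetic-texture"))
            idx += 1
    return samples


# --------------------------------------------------------------- videos

def _scene_content(rng: np.random.Generator, size: int) -> np.ndarray:
    """Feature-rich frame content (corners and blobs for ORB to latch on)."""
    img = 0.5 + 0.25 * _smooth_field(rng, size, size / 16.0)
    tex = _spot_texture(rng, size, 0.10)
    img = img + 0.3 * tex
    yy, xx = np.mgrid[0:size, 0:size].astype(float) / size
    theta = rng.uniform(0, np.pi)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    img += 0.15 * np.sign(np.sin(2 * np.pi * rng.uniform(4, 9) * u))
    return np.clip(img, 0.0, 1.0)


def generate_video(spec: SyntheticVideoSpec) -> tuple[list[np.ndarray], GroundTruth]:
    """Scene-structured frame sequence with planted sharp frames.

    Frames within a scene share content up to sub-pixel jitter and
    gaussian blur; the planted sharp frame of each scene is left
    unblurred while all others receive a blur sigma drawn from
    ``blur_sigma_range`` (whose lower bound is > 0), so the planted frame
    is strictly the sharpest of its scene.  Scene transitions swap in
    entirely new content.
    """
    master = np.random.default_rng(spec.seed)
    sharp = spec.sharp_frame_index_per_scene
    if sharp is None:
        sharp = [int(master.integers(spec.frames_per_scene))
                 for _ in range(spec.n_scenes)]
    frames: list[np.ndarray] = []
    boundaries: list[int] = []
    planted: list[int] = []
    lo, hi = spec.blur_sigma_range
    for s in range(spec.n_scenes):
        rng = np.random.default_rng(master.integers(2 ** 31))
        content = _scene_content(rng, spec.frame_size)
        if s > 0:
            boundaries.append(s * spec.frames_per_scene)
        planted.append(s * spec.frames_per_scene + sharp[s])
        for t in range(spec.frames_per_scene):
            dy, dx = rng.uniform(-1.5, 1.5, 2)
            frame = ndimage.shift(content, (dy, dx), order=1, mode="reflect")
            if t != sharp[s]:
                frame = ndimage.gaussian_filter(frame, rng.uniform(lo, hi))
            frame = frame + rng.normal(0.0, 0.01, frame.shape)
            frames.append(np.clip(frame, 0.0, 1.0))
    gt = GroundTruth(scene_boundaries=boundaries,
                     planted_keyframe_indices=planted)
    return frames, gt


# ------------------------------------------------------- highlight bank

def generate_highlight_bank(n: int, size_range: tuple[int, int] = (8, 18),
                            seed: int = 0) -> list[HighlightMask]:
    """Bank of saturated near-white highlight patches for grafting."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    lo, hi = size_range
    if not 4 <= lo <= hi:
        raise ConfigurationError("size_range must satisfy 4 <= lo <= hi")
    master = np.random.default_rng(seed)
    bank: list[HighlightMask] = []
    for _ in range(n):
        rng = np.random.default_rng(master.integers(2 ** 31))
        size = int(rng.integers(lo, hi + 1))
        blob, core = _render_highlight_blob(rng, size)
        white = rng.uniform(0.95, 1.0)
        patch = np.full((size, size, 3), white)
        patch += rng.normal(0.0, 0.01, patch.shape)
        patch = np.clip(patch, 0.9, 1.0)
        bank.append(HighlightMask(mask=core, patch=patch))
    return bank
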