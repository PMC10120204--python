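"""Video condensation: ORB-matching scene decomposition + sharpest frame.

Endoscopic video is massively redundant — thousands of near-duplicate
frames per withdrawal.  To condense a video into a small training
corpus, consecutive frames are compared by ORB keypoint matching; a drop
of the match score below a threshold starts a new scene, and from each
scene the single sharpest frame (variance of the Laplacian) is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.feature import ORB, match_descriptors

from .errors import ValidationError


@dataclass
class OrbParams:
    n_keypoints: int = 500
    max_hamming: float = 0.20  # accepted-match descriptor distance (fraction of bits)


@dataclass
class SceneDecomposition:
    frame_count: int
    boundaries: list[int]          # frame indices where a new scene starts (>0)
    keyframes: list[int]           # one frame index per scene
    match_scores: list[float]      # score between frames (t-1, t), length n-1
    no_keypoint_pairs: list[int] = field(default_factory=list)

    @property
    def scenes(self) -> list[tuple[int, int]]:
        starts = [0] + self.boundaries
        ends = self.boundaries + [self.frame_count]
        return list(zip(starts, ends))

    def to_jsonable(self) -> dict:
        return {"frame_count": self.frame_count,
                "boundaries": self.boundaries, "keyframes": self.keyframes,
                "match_scores": self.match_scores}


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        return rgb2gray(frame)
    return np.asarray(frame, dtype=np.float64)


def _orb_features(gray: np.ndarray, params: OrbParams) -> Optional[np.ndarray]:
    orb = ORB(n_keypoints=params.n_keypoints)
    try:
        orb.detect_and_extract(gray)
    except RuntimeError:  # no keypoints found
        return None
    if orb.descriptors is None or len(orb.descriptors) == 0:
        return None
    return orb.descriptors


def match_score(frame_a: np.ndarray, frame_b: np.ndarray,
                orb_params: Optional[OrbParams] = None) -> float:
    """Fraction of keypoints with an accepted cross-checked match.

    score = accepted matches / keypoints of the sparser frame; 0 when
    either frame yields no keypoints at all (featureless frames).
    """
    params = orb_params or OrbParams()
    ga, gb = _to_gray(frame_a), _to_gray(frame_b)
    if ga.shape != gb.shape:
        raise ValidationError(f"frame size mismatch: {ga.shape} vs {gb.shape}")
    da = _orb_features(ga, params)
    db = _orb_features(gb, params)
    if da is None or db is None:
        return 0.0
    matches = match_descriptors(da, db, cross_check=True,
                                max_distance=params.max_hamming)
    return float(len(matches) / min(len(da), len(db)))


def sharpness(frame: np.ndarray) -> float:
    """Variance of the Laplacian of the grayscale frame.

    Monotone decreasing under gaussian blurring; 0 for constant frames.
    """
    gray = _to_gray(frame)
    return float(ndimage.laplace(gray).var())


def select_keyframes(frames: Sequence[np.ndarray],
                     match_threshold: float = 0.15,
                     orb_params: Optional[OrbParams] = None
                     ) -> SceneDecomposition:
    """Decompose into scenes and pick the sharpest frame of each.

    A new scene starts at frame t whenever the match score between
    frames t-1 and t falls below ``match_threshold``; within a scene the
    keyframe is the argmax of :func:`sharpness` (ties to the earliest).
    """
    frames = list(frames)
    if not frames:
        raise ValidationError("empty frame list")
    params = orb_params or OrbParams()
    scores: list[float] = []
    no_kp: list[int] = []
    boundaries: list[int] = []
    for t in range(1, len(frames)):
        s = match_score(frames[t - 1], frames[t], params)
        scores.append(s)
        if s == 0.0:
            no_kp.append(t - 1)
        if s < match_threshold:
            boundaries.append(t)
    sharp = np.array([sharpness(f) for f in frames])
    keyframes = []
    for start, end in zip([0] + boundaries, boundaries + [len(frames)]):
        keyframes.append(start + int(np.argmax(sharp[start:end])))
    return SceneDecomposition(frame_count=len(frames), boundaries=boundaries,
                              keyframes=keyframes, match_scores=scores,
                              no_keypoint_pairs=no_kp)
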