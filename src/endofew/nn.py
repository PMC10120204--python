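"""Minimal convolutional encoder with analytic backpropagation.

The embedding model is the classical truncated-CNN metric encoder: a
stack of 3x3 convolution blocks, global average pooling of the final
feature map, and a single affine layer into an ``embedding_dim``-
dimensional latent space (no normalisation of the output — the triplet
margin is an absolute l2 distance, which would be meaningless on the
unit sphere).

Layers are NHWC float32; convolution is im2col + GEMM, so the whole
network runs at BLAS speed on one CPU.  Presets: ``"small"`` — three plain
conv blocks, the desk-scale default used by the test suite; ``"deep"`` —
four residual stages in the spirit of an 18-layer residual backbone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError

DTYPE = np.float32


class Layer:
    """Forward/backward unit; parameters and their gradients are aligned."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """k x k same-padding convolution (stride 1), He-initialised."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        std = np.sqrt(2.0 / (k * k * c_in))
        self.W = (std * rng.standard_normal((k * k * c_in, c_out))).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: Optional[np.ndarray] = None
        self._x_shape: Optional[tuple] = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, H, W, C = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        # (B, H, W, C, k, k) -> (B*H*W, k*k*C)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)
                                    ).reshape(B * H * W, k * k * C)
        self._cols = cols
        self._x_shape = x.shape
        y = cols @ self.W + self.b
        return y.reshape(B, H, W, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, H, W, C = self._x_shape
        k, p = self.k, self.pad
        dy_flat = dy.reshape(B * H * W, self.c_out)
        self.dW[:] = self._cols.T @ dy_flat
        self.db[:] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.W.T).reshape(B, H, W, k, k, C)
        dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + H, j:j + W, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + H, p:p + W, :] if p else dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class AvgPool2(Layer):
    """2x2 average pooling; spatial dims must be even."""

    def forward(self, x):
        B, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ValidationError(f"AvgPool2 needs even spatial dims, got {(H, W)}")
        self._in_shape = x.shape
        return x.reshape(B, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4))

    def backward(self, dy):
        B, H, W, C = self._in_shape
        dy = dy[:, :, None, :, None, :] / 4.0
        return np.broadcast_to(dy, (B, H // 2, 2, W // 2, 2, C)
                               ).reshape(B, H, W, C).astype(DTYPE)


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        B, H, W, C = self._in_shape
        return np.broadcast_to(dy[:, None, None, :] / (H * W),
                               (B, H, W, C)).astype(DTYPE)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = np.sqrt(1.0 / d_in)
        self.W = (std * rng.standard_normal((d_in, d_out))).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        return dy @ self.W.T


class ResidualStage(Layer):
    """conv3x3 -> relu -> conv3x3, plus a 1x1 projection skip; relu; pool."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2D(c_in, c_out, 3, rng)
        self.conv2 = Conv2D(c_out, c_out, 3, rng)
        self.proj = Conv2D(c_in, c_out, 1, rng)
        self.relu1 = ReLU()
        self.relu2 = ReLU()
        self.pool = AvgPool2()

    def params(self):
        return self.conv1.params() + self.conv2.params() + self.proj.params()

    def grads(self):
        return self.conv1.grads() + self.conv2.grads() + self.proj.grads()

    def forward(self, x):
        main = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        skip = self.proj.forward(x)
        return self.pool.forward(self.relu2.forward(main + skip))

    def backward(self, dy):
        d = self.relu2.backward(self.pool.backward(dy))
        dx = self.proj.backward(d)
        dx += self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Adam:
    """Adaptive-moment optimiser over a fixed parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


DEPTH_PRESETS: dict[str, tuple] = {
    "small": ("plain", (8, 16, 32)),
    "deep": ("residual", (16, 32, 64, 128)),
}

DepthSpec = Union[str, Sequence[int]]


@dataclass
class EmbeddingModel:
    """Encoder contract: image (or batch) -> ``embedding_dim`` real vector."""

    net: Sequential
    embedding_dim: int
    depth_spec: DepthSpec
    seed: int
    class_vocabulary: list[str] = field(default_factory=list)

    def embed_batch(self, x: np.ndarray) -> np.ndarray:
        """x: (B, H, W, 3) in [0,1] -> (B, embedding_dim) float64."""
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValidationError(f"expected (B, H, W, 3) input, got {x.shape}")
        return self.net.forward(x.astype(DTYPE)).astype(np.float64)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.net.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.net.params(), weights):
            p[:] = w

    def copy(self) -> "EmbeddingModel":
        clone = build_encoder(self.depth_spec, self.embedding_dim, seed=self.seed)
        clone.set_weights(self.get_weights())
        clone.class_vocabulary = list(self.class_vocabulary)
        return clone


def build_encoder(depth_spec: DepthSpec = "deep", embedding_dim: int = 64,
                  pretrained_backbone: Optional[str | Path] = None,
                  seed: int = 0) -> EmbeddingModel:
    """Construct the encoder.

    ``depth_spec`` is a preset name (``"small"``, ``"deep"``) or an explicit
    tuple of channel widths, one plain conv block per entry.  Every block
    halves the spatial resolution, so the input side length must be
    divisible by 2**n_blocks.  ``pretrained_backbone`` optionally names a
    checkpoint whose weights are copied in (see :func:`load_checkpoint`).
    """
    if embedding_dim < 1:
        raise ValidationError("embedding_dim must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(depth_spec, str):
        if depth_spec not in DEPTH_PRESETS:
            raise ValidationError(f"unknown depth preset {depth_spec!r}")
        kind, channels = DEPTH_PRESETS[depth_spec]
    else:
        kind, channels = "plain", tuple(int(c) for c in depth_spec)
        if not channels:
            raise ValidationError("depth_spec channel tuple is empty")
    layers: list[Layer] = []
    c_prev = 3
    for c in channels:
        if kind == "residual":
            layers.append(ResidualStage(c_prev, c, rng))
        else:
            layers += [Conv2D(c_prev, c, 3, rng), ReLU(), AvgPool2()]
        c_prev = c
    layers.append(GlobalAvgPool())
    layers.append(Dense(c_prev, embedding_dim, rng))
    model = EmbeddingModel(net=Sequential(layers), embedding_dim=embedding_dim,
                           depth_spec=depth_spec, seed=seed)
    if pretrained_backbone is not None:
        src = load_checkpoint(pretrained_backbone)
        model.set_weights(src.get_weights())
        model.class_vocabulary = list(src.class_vocabulary)
    return model


def save_checkpoint(model: EmbeddingModel, path: str | Path) -> None:
    """Weights + architecture config in one ``.npz`` container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "embedding_dim": model.embedding_dim,
        "depth_spec": (model.depth_spec if isinstance(model.depth_spec, str)
                       else list(model.depth_spec)),
        "seed": model.seed,
        "class_vocabulary": model.class_vocabulary,
    }
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> EmbeddingModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        depth = meta["depth_spec"]
        depth = depth if isinstance(depth, str) else tuple(depth)
        model = build_encoder(depth, meta["embedding_dim"], seed=meta["seed"])
        n = len(model.get_weights())
        model.set_weights([data[f"w{i}"] for i in range(n)])
        model.class_vocabulary = list(meta["class_vocabulary"])
    return model
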