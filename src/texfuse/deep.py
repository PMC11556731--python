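"""Pluggable image-to-vector ("dynamic") feature extractors.

The binding contract is small: an extractor exposes ``output_dim`` and a
deterministic batched image -> vector map.  Anything honoring it plugs into
the pipeline, from trivial stubs to the default convolutional topology.

The default topology, ``vgg16_truncated_dense1024``, mirrors a VGG-16-style
feature extractor: thirteen 3x3 convolution layers in five blocks
(64-64 / 128-128 / 256x3 / 512x3 / 512x3) with 2x2 max pooling, then
flatten -> dense(1024) -> ReLU -> dense(1024); the second dense layer's
linear output is the 1024-dimensional feature tap (the classification head
that would follow is irrelevant at extraction time).  It runs feed-forward
in NumPy (im2col convolutions on BLAS matmuls), so it needs no GPU and no
network access.  Weights are either drawn from a seeded He-normal
initializer -- random projections through a deep architecture are a
legitimate, fully reproducible feature map for desk-scale experiments -- or
loaded from an ``.npz`` file produced by :meth:`VGGExtractor.save_weights`.

Grayscale input is replicated to three channels and scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .types import CLASS_COLUMN, Image, ParameterError

VGG16_CHANNELS = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
                  512, 512, 512, "M", 512, 512, 512, "M")


@dataclass
class ExtractorSpec:
    """Configuration of a deep feature extractor.

    ``weights`` is ``("random", seed)`` or ``("pretrained", path)``;
    ``width_scale`` multiplies every convolutional channel count (1.0 is the
    full topology; smaller values give a thin, fast variant for experiments).
    """

    topology: str = "vgg16_truncated_dense1024"
    output_dim: int = 1024
    weights: tuple = ("random", 0)
    input_size: tuple[int, int] = (224, 224)
    width_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ParameterError("output_dim must be >= 1")
        if self.weights[0] not in ("random", "pretrained"):
            raise ParameterError("weights must be ('random', seed) or ('pretrained', path)")
        if not (0 < self.width_scale <= 1):
            raise ParameterError("width_scale must lie in (0, 1]")


@runtime_checkable
class Extractor(Protocol):
    """The extractor contract: an output dimension and a batched image map."""

    output_dim: int

    def transform(self, batch: np.ndarray) -> np.ndarray:
        """Map a (n, H, W) uint8 batch to an (n, output_dim) float array."""
        ...


def _as_batch(images: Iterable[Image] | np.ndarray) -> tuple[np.ndarray, list[str], list]:
    if isinstance(images, np.ndarray):
        batch = images if images.ndim == 3 else images[None]
        n = batch.shape[0]
        return batch, [str(i) for i in range(n)], [None] * n
    imgs = list(images)
    return (
        np.stack([im.pixels for im in imgs]),
        [im.id for im in imgs],
        [im.label for im in imgs],
    )


class MeanIntensityExtractor:
    """Stub extractor: the per-image mean intensity (output_dim = 1)."""

    output_dim = 1

    def transform(self, batch: np.ndarray) -> np.ndarray:
        return batch.reshape(batch.shape[0], -1).mean(axis=1, dtype=np.float64)[:, None]


class RandomProjectionExtractor:
    """Seeded Gaussian random projection of the flattened image, tanh-squashed.

    Fast and distance-preserving (Johnson-Lindenstrauss), which makes it the
    practical random-weights extractor for large synthetic runs.
    """

    def __init__(self, input_size: tuple[int, int], output_dim: int, seed: int):
        self.output_dim = int(output_dim)
        self.input_size = tuple(input_size)
        d = input_size[0] * input_size[1]
        rng = np.random.default_rng(seed)
        self._w = (rng.standard_normal((d, output_dim)) / np.sqrt(d)).astype(np.float32)

    def transform(self, batch: np.ndarray) -> np.ndarray:
        if batch.shape[1:] != self.input_size:
            raise ParameterError(
                f"expected images of shape {self.input_size}, got {batch.shape[1:]}"
            )
        x = (batch.reshape(batch.shape[0], -1).astype(np.float32)) / 255.0
        return np.tanh(x @ self._w)


def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution: x (H, W, Cin), w (3, 3, Cin, Cout)."""
    xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    windows = sliding_window_view(xp, (3, 3), axis=(0, 1))  # (H, W, Cin, 3, 3)
    return np.tensordot(windows, w, axes=([3, 4, 2], [0, 1, 2])) + b


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    return x[: h2 * 2, : w2 * 2].reshape(h2, 2, w2, 2, c).max(axis=(1, 3))


class VGGExtractor:
    """The default convolutional extractor (see module docstring)."""

    def __init__(self, spec: ExtractorSpec):
        self.spec = spec
        self.output_dim = spec.output_dim
        self.input_size = tuple(spec.input_size)
        self._channels = [
            c if c == "M" else max(1, int(round(c * spec.width_scale)))
            for c in VGG16_CHANNELS
        ]
        h, w = self.input_size
        pools = self._channels.count("M")
        if min(h, w) < 2**pools:
            raise ParameterError(
                f"input_size {self.input_size} too small for {pools} pooling stages"
            )
        self._flat_dim = (h // 2**pools) * (w // 2**pools) * self._channels[-2]
        mode, arg = spec.weights
        if mode == "random":
            self._init_random(int(arg))
        else:
            self._load(arg)

    # -- weights ---------------------------------------------------------

    def _layer_shapes(self) -> list[tuple[str, tuple]]:
        shapes: list[tuple[str, tuple]] = []
        cin = 3
        for idx, c in enumerate(self._channels):
            if c == "M":
                continue
            shapes.append((f"conv{idx}", (3, 3, cin, c)))
            cin = c
        shapes.append(("dense0", (self._flat_dim, 1024)))
        shapes.append(("dense1", (1024, self.output_dim)))
        return shapes

    def _init_random(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        self._weights: dict[str, np.ndarray] = {}
        for name, shape in self._layer_shapes():
            fan_in = int(np.prod(shape[:-1]))
            self._weights[name] = (
                rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            self._weights[name + "_b"] = np.zeros(shape[-1], dtype=np.float32)

    def _load(self, path) -> None:
        p = Path(path)
        if not p.exists():
            raise IOError(
                f"weights file {p} not found; pass weights=('random', seed) to use "
                "seeded random weights, or save weights first with save_weights()"
            )
        with np.load(p) as npz:
            self._weights = {k: npz[k] for k in npz.files}
        for name, shape in self._layer_shapes():
            if name not in self._weights or self._weights[name].shape != shape:
                raise IOError(
                    f"weights file {p} does not match topology: layer {name} "
                    f"expected shape {shape}"
                )

    def save_weights(self, path) -> None:
        np.savez(path, **self._weights)

    # -- forward ---------------------------------------------------------

    def _forward_one(self, pixels: np.ndarray) -> np.ndarray:
        x = np.repeat((pixels.astype(np.float32) / 255.0)[:, :, None], 3, axis=2)
        for idx, c in enumerate(self._channels):
            if c == "M":
                x = _maxpool2(x)
            else:
                name = f"conv{idx}"
                x = _conv3x3(x, self._weights[name], self._weights[name + "_b"])
                np.maximum(x, 0.0, out=x)
        x = x.reshape(-1)
        x = x @ self._weights["dense0"] + self._weights["dense0_b"]
        np.maximum(x, 0.0, out=x)
        return x @ self._weights["dense1"] + self._weights["dense1_b"]

    def transform(self, batch: np.ndarray) -> np.ndarray:
        if batch.shape[1:] != self.input_size:
            raise ParameterError(
                f"expected images of shape {self.input_size}, got {batch.shape[1:]}"
            )
        return np.stack([self._forward_one(img) for img in batch])


def build_extractor(spec: ExtractorSpec) -> Extractor:
    """Construct an extractor from its spec.

    Topologies: ``vgg16_truncated_dense1024`` (default), ``random_projection``
    and ``mean_intensity`` (a 1-dimensional stub).
    """
    if spec.topology == "vgg16_truncated_dense1024":
        return VGGExtractor(spec)
    if spec.topology == "random_projection":
        mode, arg = spec.weights
        if mode != "random":
            raise ParameterError("random_projection supports only random weights")
        return RandomProjectionExtractor(spec.input_size, spec.output_dim, int(arg))
    if spec.topology == "mean_intensity":
        return MeanIntensityExtractor()
    raise ParameterError(f"unknown topology {spec.topology!r}")


def extract(extractor: Extractor, images: Iterable[Image] | np.ndarray) -> pd.DataFrame:
    """Deep feature table: one row per image in input order.

    Columns are ``deep_0001 .. deep_NNNN`` plus the class column carried from
    the image labels; the index is the image id.
    """
    batch, ids, labels = _as_batch(images)
    vectors = extractor.transform(batch)
    if vectors.shape != (batch.shape[0], extractor.output_dim):
        raise ParameterError(
            f"extractor returned shape {vectors.shape}, expected "
            f"({batch.shape[0]}, {extractor.output_dim})"
        )
    width = max(4, len(str(extractor.output_dim)))
    cols = [f"deep_{i + 1:0{width}d}" for i in range(extractor.output_dim)]
    table = pd.DataFrame(np.asarray(vectors, dtype=np.float64), columns=cols)
    table.index = pd.Index(ids, name="id")
    table[CLASS_COLUMN] = labels
    return table
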