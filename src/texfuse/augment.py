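"""Parameterized augmentation transforms and augmentation-based class balancing.

Twelve transforms are supported, each with a parameter range and a firing
probability.  One augmented image is produced by passing the original through
a freshly sampled pipeline in which every transform fires independently with
its probability; drawn parameters are logged so any augmented image can be
reproduced.  Class balancing oversamples each minority class with augmented
copies of randomly chosen originals until every class matches the majority
class count; originals are never removed or mutated.

Geometric transforms resample bilinearly with a reflected border; all outputs
keep the input shape and the 8-bit [0, 255] contract.  "Polarize" (a
saturation adjustment in color imagery) is rendered for grayscale as contrast
scaling about the image mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .types import Dataset, Image, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class TransformSpec:
    """One augmentation transform: name, parameter ranges and probability."""

    name: str
    params: dict[str, tuple[float, float]] = field(default_factory=dict)
    probability: float = 0.2

    def __post_init__(self) -> None:
        if self.name not in _TRANSFORMS:
            raise ParameterError(
                f"unknown transform {self.name!r}; choose from {sorted(_TRANSFORMS)}"
            )
        if not (0.0 <= self.probability <= 1.0):
            raise ParameterError("probability must lie in [0, 1]")


def default_transform_specs() -> list[TransformSpec]:
    """The default bank of twelve transforms with their ranges/probabilities."""
    return [
        TransformSpec("rotation", {"angle": (-50.0, 20.0)}, 0.2),
        TransformSpec("hflip", {}, 1.0),
        TransformSpec("vflip", {}, 1.0),
        TransformSpec("shear", {"angle": (-40.0, 40.0)}, 0.2),
        TransformSpec("gamma_contrast", {"gamma": (0.5, 2.0)}, 0.2),
        TransformSpec("sigmoid_contrast", {"gain": (5.0, 10.0)}, 0.2),
        TransformSpec("linear_contrast", {"delta": (-0.2, 0.2)}, 0.2),
        TransformSpec("elastic", {"alpha": (60.0, 60.0), "sigma": (4.0, 4.0)}, 0.2),
        TransformSpec("polar", {"magnitude": (-0.2, 0.7)}, 0.2),
        TransformSpec("jigsaw", {"grid": (4, 8), "interpolation": (3, 7)}, 0.2),
        TransformSpec("invert", {}, 1.0),
        TransformSpec("polarize", {"factor": (0.5, 2.0)}, 0.2),
    ]


def _round_u8(a: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(a + 0.5), 0, 255).astype(np.uint8)


def _warp(pixels: np.ndarray, tform) -> np.ndarray:
    out = sktransform.warp(
        pixels.astype(np.float64), tform, order=1, mode="reflect", preserve_range=True
    )
    return _round_u8(out)


def _t_rotation(pixels: np.ndarray, rng: np.random.Generator, angle: float) -> np.ndarray:
    if angle == 0.0:
        return pixels.copy()
    out = sktransform.rotate(
        pixels.astype(np.float64), angle, resize=False, order=1, mode="reflect",
        preserve_range=True,
    )
    return _round_u8(out)


def _t_hflip(pixels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.flip(pixels, axis=1).copy()


def _t_vflip(pixels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.flip(pixels, axis=0).copy()


def _t_shear(pixels: np.ndarray, rng: np.random.Generator, angle: float) -> np.ndarray:
    if angle == 0.0:
        return pixels.copy()
    h, w = pixels.shape
    # Shear about the image center so content does not slide off one edge.
    center = np.array([w / 2.0, h / 2.0])
    tform = (
        sktransform.AffineTransform(translation=-center)
        + sktransform.AffineTransform(shear=np.deg2rad(angle))
        + sktransform.AffineTransform(translation=center)
    )
    return _warp(pixels, tform.inverse)


def _t_gamma(pixels: np.ndarray, rng: np.random.Generator, gamma: float) -> np.ndarray:
    return _round_u8(255.0 * (pixels / 255.0) ** gamma)


def _t_sigmoid(pixels: np.ndarray, rng: np.random.Generator, gain: float) -> np.ndarray:
    x = pixels / 255.0
    return _round_u8(255.0 / (1.0 + np.exp(gain * (0.5 - x))))


def _t_linear(pixels: np.ndarray, rng: np.random.Generator, delta: float) -> np.ndarray:
    return _round_u8(pixels.astype(np.float64) + 255.0 * delta)


def _t_elastic(
    pixels: np.ndarray, rng: np.random.Generator, alpha: float, sigma: float
) -> np.ndarray:
    shape = pixels.shape
    dx = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), sigma, mode="reflect") * alpha
    dy = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), sigma, mode="reflect") * alpha
    rr, cc = np.indices(shape, dtype=np.float64)
    out = ndimage.map_coordinates(
        pixels.astype(np.float64), [rr + dy, cc + dx], order=1, mode="reflect"
    )
    return _round_u8(out)


def _t_polar(pixels: np.ndarray, rng: np.random.Generator, magnitude: float) -> np.ndarray:
    # Radial distortion about the center: sample the source at radius
    # r * (1 + magnitude), a polar-coordinate zoom in/out.
    h, w = pixels.shape
    rr, cc = np.indices((h, w), dtype=np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    scale = 1.0 + magnitude
    out = ndimage.map_coordinates(
        pixels.astype(np.float64),
        [cy + (rr - cy) * scale, cx + (cc - cx) * scale],
        order=1,
        mode="reflect",
    )
    return _round_u8(out)


def _t_jigsaw(
    pixels: np.ndarray, rng: np.random.Generator, grid: float, interpolation: float
) -> np.ndarray:
    # Permute the g x g blocks of the largest top-left region divisible by g;
    # margins (at most g-1 pixels) are left in place.  The drawn interpolation
    # parameter selects nothing for grayscale block moves and is logged only.
    g = int(grid)
    h, w = pixels.shape
    bh, bw = h // g, w // g
    if bh < 1 or bw < 1:
        return pixels.copy()
    out = pixels.copy()
    region = out[: g * bh, : g * bw]
    blocks = region.reshape(g, bh, g, bw).transpose(0, 2, 1, 3).reshape(g * g, bh, bw)
    perm = rng.permutation(g * g)
    shuffled = blocks[perm].reshape(g, g, bh, bw).transpose(0, 2, 1, 3).reshape(g * bh, g * bw)
    out[: g * bh, : g * bw] = shuffled
    return out


def _t_invert(pixels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (255 - pixels.astype(np.int16)).astype(np.uint8)


def _t_polarize(pixels: np.ndarray, rng: np.random.Generator, factor: float) -> np.ndarray:
    mean = pixels.mean()
    return _round_u8(mean + factor * (pixels.astype(np.float64) - mean))


_TRANSFORMS = {
    "rotation": _t_rotation,
    "hflip": _t_hflip,
    "vflip": _t_vflip,
    "shear": _t_shear,
    "gamma_contrast": _t_gamma,
    "sigmoid_contrast": _t_sigmoid,
    "linear_contrast": _t_linear,
    "elastic": _t_elastic,
    "polar": _t_polar,
    "jigsaw": _t_jigsaw,
    "invert": _t_invert,
    "polarize": _t_polarize,
}

_INT_PARAMS = {"grid", "interpolation"}


def _draw_params(spec: TransformSpec, rng: np.random.Generator) -> dict[str, float]:
    params: dict[str, float] = {}
    for name, (lo, hi) in spec.params.items():
        if name in _INT_PARAMS:
            params[name] = int(rng.integers(int(lo), int(hi) + 1))
        else:
            params[name] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return params


def apply_transform(image: Image, spec: TransformSpec, rng: np.random.Generator) -> Image:
    """Apply one transform: with probability 1 - p the image passes through.

    Parameter values are drawn uniformly from the spec's ranges.
    """
    if rng.uniform() >= spec.probability:
        return image.with_pixels(image.pixels.copy())
    params = _draw_params(spec, rng)
    out = _TRANSFORMS[spec.name](image.pixels, rng, **params)
    return image.with_pixels(out)


def sample_pipeline(
    specs: list[TransformSpec], rng: np.random.Generator
) -> list[tuple[TransformSpec, dict[str, float]]]:
    """Draw one augmentation pipeline: each spec fires independently.

    Returns the fired (spec, drawn parameters) pairs in listed order; the
    parameter log makes the sampled pipeline reproducible.
    """
    if not specs:
        raise ParameterError("need at least one TransformSpec")
    pipeline = []
    for spec in specs:
        if rng.uniform() < spec.probability:
            pipeline.append((spec, _draw_params(spec, rng)))
    return pipeline


def run_pipeline_on_image(
    image: Image,
    pipeline: list[tuple[TransformSpec, dict[str, float]]],
    rng: np.random.Generator,
) -> Image:
    """Apply an already-sampled pipeline to an image."""
    pixels = image.pixels
    for spec, params in pipeline:
        pixels = _TRANSFORMS[spec.name](pixels, rng, **params)
    return image.with_pixels(pixels.copy())


def augment_image(
    image: Image, specs: list[TransformSpec], rng: np.random.Generator, id: str = ""
) -> tuple[Image, list[dict]]:
    """One augmented copy via a freshly sampled pipeline, plus its audit log."""
    pipeline = sample_pipeline(specs, rng)
    out = run_pipeline_on_image(image, pipeline, rng)
    log = [{"transform": s.name, "params": p} for s, p in pipeline]
    return Image(pixels=out.pixels, label=image.label, id=id or image.id), log


def balance_classes(
    dataset: Dataset,
    specs: list[TransformSpec] | None = None,
    seed: int = 0,
) -> Dataset:
    """Equalize class counts to the majority class by augmentation.

    Minority-class deficits are filled with augmented copies of uniformly
    drawn (with replacement) originals of that class.  Originals are retained
    unchanged; an already-balanced dataset comes back with zero additions.
    Deterministic given (dataset, specs, seed), independent of class order.
    """
    if specs is None:
        specs = default_transform_specs()
    counts = dataset.class_counts
    if not counts or any(label is None for label in counts):
        raise ParameterError("balancing requires a labelled, non-empty dataset")
    target = max(counts.values())
    by_class: dict[str, list[Image]] = {}
    for img in dataset:
        by_class.setdefault(img.label, []).append(img)
    out = Dataset(images=list(dataset.images))
    for ci, label in enumerate(sorted(counts)):
        deficit = target - counts[label]
        sources = by_class[label]
        for i in range(deficit):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(ci, i))
            )
            src = sources[int(rng.integers(len(sources)))]
            aug, _ = augment_image(src, specs, rng, id=f"{label}_aug_{i:05d}")
            out.images.append(aug)
    logger.info("balanced class counts: %s", out.class_counts)
    return out
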