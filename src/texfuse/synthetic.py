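"""Synthetic texture images and feature tables with known statistical structure.

Every downstream stage of the pipeline (preprocessing, GLCM features, feature
selection, classification) is testable on data whose ground truth is known by
construction.  Two generators are provided:

* :func:`generate_texture_image` / :func:`generate_dataset` -- labelled 8-bit
  grayscale images whose classes differ in second-order texture statistics.
  Three texture families are supported: Gaussian-smoothed white noise (the
  smoothing scale sets the spatial correlation length, hence the short-range
  GLCM contrast), a checkerboard (period = smoothing scale) and random blob
  fields.  Per-class image counts are configurable, so the heavy class
  imbalance of real multi-source radiograph collections can be mirrored.

* :func:`generate_feature_table` -- tabular fixtures for feature selection:
  "informative" features get distinct per-class means, "uninformative" ones a
  single shared mean, so the exact set a class-conditional-mean filter should
  recover is known.

Reproducibility: a single integer seed fans out to independent per-image
substreams keyed by (class index, image index) through ``np.random.SeedSequence``,
so regenerating any single image does not depend on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import CLASS_COLUMN, Dataset, Image, ParameterError

FAMILIES = ("smoothed-noise", "checker", "blob")

_MID = 128.0  # base gray level all families oscillate around


@dataclass
class TextureClassSpec:
    """Parameters of one synthetic texture class.

    smoothing_scale : pixels; correlation length (blur sigma, checker period,
        blob radius).  amplitude : peak-to-peak intensity swing of the texture
        signal.  noise_sd : sd of i.i.d. additive pixel noise.  Intensities are
        clipped (not wrapped) to [0, 255] and stored 8-bit.
    """

    label: str
    family: str = "smoothed-noise"
    smoothing_scale: float = 2.0
    amplitude: float = 120.0
    noise_sd: float = 8.0
    size: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown texture family {self.family!r}; choose from {FAMILIES}")
        if self.smoothing_scale <= 0:
            raise ParameterError("smoothing_scale must be > 0")
        h, w = self.size
        if h < 16 or w < 16:
            raise ParameterError(f"size must be at least (16, 16), got {self.size}")
        if not (0 <= self.amplitude <= 255):
            raise ParameterError("amplitude must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


def _smoothed_noise(spec: TextureClassSpec, rng: np.random.Generator) -> np.ndarray:
    field_ = rng.standard_normal(spec.size)
    field_ = ndimage.gaussian_filter(field_, sigma=spec.smoothing_scale, mode="reflect")
    sd = field_.std()
    if sd > 0:
        field_ /= sd
    return _MID + (spec.amplitude / 2.0) * field_


def _checker(spec: TextureClassSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    period = max(1, int(round(spec.smoothing_scale)))
    rr, cc = np.indices((h, w))
    phase = rng.integers(0, 2)
    parity = ((rr // period + cc // period + phase) % 2).astype(np.float64)
    return _MID + (spec.amplitude / 2.0) * (2.0 * parity - 1.0)


def _blob(spec: TextureClassSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.size
    radius = max(1.0, float(spec.smoothing_scale))
    # Blob density chosen so roughly a third of the area is covered.
    n_blobs = max(1, int(0.35 * h * w / (np.pi * radius**2)))
    img = np.full((h, w), _MID - spec.amplitude / 2.0)
    rr, cc = np.indices((h, w))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        mask = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
        img[mask] = _MID + spec.amplitude / 2.0
    return img


_GENERATORS = {"smoothed-noise": _smoothed_noise, "checker": _checker, "blob": _blob}


def generate_texture_image(
    spec: TextureClassSpec, rng: np.random.Generator, id: str = ""
) -> Image:
    """Draw one labelled texture image from ``spec`` using ``rng``.

    Identical spec + identically seeded rng give bit-identical images.
    """
    signal = _GENERATORS[spec.family](spec, rng)
    if spec.noise_sd > 0:
        signal = signal + spec.noise_sd * rng.standard_normal(spec.size)
    pixels = np.clip(np.floor(signal + 0.5), 0, 255).astype(np.uint8)
    return Image(pixels=pixels, label=spec.label, id=id)


def generate_dataset(
    specs: list[TextureClassSpec],
    counts: dict[str, int] | list[int],
    seed: int,
) -> Dataset:
    """Generate a labelled dataset with exactly the requested per-class counts.

    ``counts`` maps class label to image count (or lists counts in spec order).
    Images are reproducible from ``seed`` independently of generation order.
    """
    if not specs:
        raise ParameterError("need at least one TextureClassSpec")
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise ParameterError("duplicate class labels in specs")
    if not isinstance(counts, dict):
        if len(counts) != len(specs):
            raise ParameterError("counts list must align with specs")
        counts = dict(zip(labels, counts))
    missing = set(counts) - set(labels)
    if missing:
        raise ParameterError(f"counts given for unknown labels: {sorted(missing)}")
    images: list[Image] = []
    for ci, spec in enumerate(specs):
        n = int(counts.get(spec.label, 0))
        if n < 1:
            raise ParameterError(f"count for class {spec.label!r} must be >= 1")
        for i in range(n):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(ci, i)))
            images.append(generate_texture_image(spec, rng, id=f"{spec.label}_{i:05d}"))
    return Dataset(images=images)


@dataclass
class FeatureTableSpec:
    """Specification of a tabular feature fixture with known class structure.

    ``informative`` lists (name, per-class means, sd) with at least two
    distinct means; ``uninformative`` lists (name, shared mean, sd).
    """

    classes: list[str]
    n_per_class: int
    informative: list[tuple[str, list[float], float]] = field(default_factory=list)
    uninformative: list[tuple[str, float, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ParameterError("need at least one class")
        if len(set(self.classes)) != len(self.classes):
            raise ParameterError("duplicate class labels")
        if self.n_per_class < 1:
            raise ParameterError("n_per_class must be >= 1")
        names = [n for n, *_ in self.informative] + [n for n, *_ in self.uninformative]
        if len(set(names)) != len(names):
            raise ParameterError("duplicate feature names")
        if not names:
            raise ParameterError("need at least one feature")
        for name, means, sd in self.informative:
            if len(means) != len(self.classes):
                raise ParameterError(f"feature {name!r}: need one mean per class")
            if len(set(means)) < 2:
                raise ParameterError(f"informative feature {name!r} needs >= 2 distinct means")
            if sd < 0:
                raise ParameterError("sd must be >= 0")
        for name, _, sd in self.uninformative:
            if sd < 0:
                raise ParameterError("sd must be >= 0")


def generate_feature_table(spec: FeatureTableSpec) -> pd.DataFrame:
    """Draw a labelled feature table: one Gaussian draw per (row, feature).

    Returns a DataFrame with the feature columns in declaration order
    (informative first) and the class column last.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_per_class, len(spec.classes)
    columns: dict[str, np.ndarray] = {}
    for name, means, sd in spec.informative:
        columns[name] = np.concatenate(
            [m + sd * rng.standard_normal(n) for m in means]
        )
    for name, mean, sd in spec.uninformative:
        columns[name] = mean + sd * rng.standard_normal(n * k)
    table = pd.DataFrame(columns)
    table[CLASS_COLUMN] = np.repeat(spec.classes, n)
    return table
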