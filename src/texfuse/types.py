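"""Core in-memory containers shared across the pipeline.

The unit flowing through preprocessing and augmentation is an :class:`Image`:
a labelled 2-D grid of 8-bit intensities.  Collections of images are held in a
:class:`Dataset`.  Feature tables are plain :class:`pandas.DataFrame` objects
with named feature columns, a final ``class`` column and the image id as index
(see :mod:`texfuse.mdfs` for the conventions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

CLASS_COLUMN = "class"

# ITU-R BT.601 luma weights, matching common 8-bit grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


class ParameterError(ValueError):
    """An operation was called with parameters violating its contract."""


def to_grayscale_u8(pixels: np.ndarray) -> np.ndarray:
    """Coerce an array to a 2-D uint8 intensity grid.

    Color (H, W, 3) or (H, W, 4) input is reduced by BT.601 luminance; float
    input is rounded half-up and clipped to [0, 255].
    """
    a = np.asarray(pixels)
    if a.ndim == 3:
        a = a[..., :3].astype(np.float64) @ _LUMA
    if a.ndim != 2:
        raise ParameterError(f"expected a 2-D image, got shape {a.shape}")
    if a.dtype != np.uint8:
        a = np.clip(np.floor(a.astype(np.float64) + 0.5), 0, 255).astype(np.uint8)
    return a


@dataclass
class Image:
    """A labelled 2-D 8-bit grayscale image.

    Invariants: ``pixels`` is H x W uint8 with H, W >= 1; intensities therefore
    lie in [0, 255] by construction.
    """

    pixels: np.ndarray
    label: str | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = to_grayscale_u8(self.pixels)
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ParameterError("image must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "Image":
        """A copy of this image with new pixel data, same label/id."""
        return replace(self, pixels=pixels)


@dataclass
class Dataset:
    """An ordered collection of labelled images."""

    images: list[Image] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not isinstance(self.images, list):
            self.images = list(self.images)

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(img.label for img in self.images))

    @property
    def labels(self) -> list[str]:
        return [img.label for img in self.images]

    def extend(self, images: Iterable[Image]) -> None:
        self.images.extend(images)
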