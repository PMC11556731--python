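"""Image conditioning: area-interpolation resize, median denoising, equalization.

The three stages run in the fixed order resize -> median -> equalize and each
preserves the 8-bit contract (uint8 output in [0, 255]).  All float
intermediates are rounded half-up so results are bit-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import Image, ParameterError


@dataclass
class PreprocessConfig:
    out_size: tuple[int, int] = (224, 224)
    median_kernel: int = 3
    equalize: bool = True

    def __post_init__(self) -> None:
        h, w = self.out_size
        if h < 1 or w < 1:
            raise ParameterError(f"out_size must be positive, got {self.out_size}")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ParameterError("median_kernel must be an odd integer >= 1")


def _round_u8(a: np.ndarray) -> np.ndarray:
    return np.clip(np.floor(a + 0.5), 0, 255).astype(np.uint8)


def _area_weights(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic matrix of fractional pixel-area overlaps (1-D).

    Output cell j spans [j*s, (j+1)*s) in input coordinates with s = n_in/n_out;
    each input cell contributes in proportion to its overlap with that span.
    For integer downscale factors this is an exact block average.
    """
    scale = n_in / n_out
    W = np.zeros((n_out, n_in))
    for j in range(n_out):
        lo, hi = j * scale, (j + 1) * scale
        i0, i1 = int(np.floor(lo)), min(int(np.ceil(hi)), n_in)
        for i in range(i0, i1):
            W[j, i] = min(hi, i + 1) - max(lo, i)
    return W / scale


def resize_area(image: Image | np.ndarray, out_size: tuple[int, int]):
    """Resize by pixel-area averaging ("inter-area" interpolation).

    Downscaling by an integer factor k reduces each k x k block to its mean;
    non-integer factors use exact fractional-area overlap weights, separably
    per axis.  Resizing to the input's own shape is the identity.
    """
    pixels = image.pixels if isinstance(image, Image) else np.asarray(image)
    h_out, w_out = out_size
    if h_out < 1 or w_out < 1:
        raise ParameterError(f"out_size must be positive, got {out_size}")
    h, w = pixels.shape
    if (h, w) == (h_out, w_out):
        out = pixels.copy()
    else:
        wr = _area_weights(h, h_out)
        wc = _area_weights(w, w_out)
        out = _round_u8(wr @ pixels.astype(np.float64) @ wc.T)
    return image.with_pixels(out) if isinstance(image, Image) else out


def median_denoise(image: Image | np.ndarray, kernel: int = 3):
    """Median filter with a kernel x kernel window and reflect border handling.

    A rank filter: every output pixel is a member of its input neighborhood,
    so the [0, 255] range is preserved automatically.  kernel = 1 is the
    identity.
    """
    pixels = image.pixels if isinstance(image, Image) else np.asarray(image)
    if kernel < 1 or kernel % 2 == 0:
        raise ParameterError("median kernel must be an odd integer >= 1")
    if kernel > min(pixels.shape):
        raise ParameterError(
            f"median kernel {kernel} exceeds smallest image dimension {min(pixels.shape)}"
        )
    out = pixels if kernel == 1 else ndimage.median_filter(pixels, size=kernel, mode="reflect")
    out = out.astype(np.uint8, copy=True)
    return image.with_pixels(out) if isinstance(image, Image) else out


def equalize_intensity(image: Image | np.ndarray):
    """Global histogram equalization on the 256-level grid.

    Uses the classic CDF-min lookup table
    ``lut[v] = round(255 * (cdf[v] - cdf_min) / (N - cdf_min))``, which is
    monotone in the input level (rank order preserved) and maps a constant
    image to itself (the degenerate N == cdf_min case).
    """
    pixels = image.pixels if isinstance(image, Image) else np.asarray(image)
    hist = np.bincount(pixels.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    n = cdf[-1]
    cdf_min = cdf[hist > 0][0]
    if n == cdf_min:  # single gray level: leave it where it is
        out = pixels.copy()
    else:
        lut = np.floor(255.0 * (cdf - cdf_min) / (n - cdf_min) + 0.5).astype(np.uint8)
        out = lut[pixels]
    return image.with_pixels(out) if isinstance(image, Image) else out


def preprocess_pipeline(image: Image, config: PreprocessConfig = PreprocessConfig()) -> Image:
    """resize -> median denoise -> equalize, per the configured parameters."""
    out = resize_area(image, config.out_size)
    if config.median_kernel > 1:
        out = median_denoise(out, config.median_kernel)
    if config.equalize:
        out = equalize_intensity(out)
    return out
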