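"""Gray-level co-occurrence matrices and the 25-feature static texture vector.

A GLCM tabulates how often pairs of quantized gray levels co-occur at a fixed
pixel offset (distance d, angle theta); Haralick-style scalar statistics of
the normalized matrix summarize texture.  The static descriptor used by the
pipeline is a fixed, ordered set of 25 such statistics, averaged over the four
standard angles {0, 45, 90, 135} degrees at each configured distance.

Conventions: entropies use base-2 logarithms with 0*log(0) := 0; matrices are
symmetric (transpose-added) and normalized to sum 1 by default; quantization
uses uniform bin widths over [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import CLASS_COLUMN, Image, ParameterError

#: The fixed, ordered 25-feature list of the static texture descriptor.
FEATURE_NAMES: tuple[str, ...] = (
    "contrast",
    "dissimilarity",
    "homogeneity",              # inverse difference moment, 1/(1+(i-j)^2) weighting
    "energy",                   # angular second moment, sum p^2
    "entropy",
    "correlation",
    "variance",                 # sum-of-squares variance about the row-marginal mean
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",                     # information measure of correlation 1
    "imc2",                     # information measure of correlation 2
    "autocorrelation",
    "cluster_shade",
    "cluster_prominence",
    "maximum_probability",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
    "max_correlation_coefficient",
    "mean_x",                   # row-marginal mean
    "mean_y",                   # column-marginal mean
    "marginal_entropy",         # entropy of the row marginal
)

ANGLES_DEFAULT = (0, 45, 90, 135)

# unit offsets (row, col), rows growing downward; 90 deg points up
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCM:
    """A co-occurrence matrix for one (distance, angle) offset."""

    matrix: np.ndarray
    levels: int
    distance: int
    angle: int
    symmetric: bool
    normalized: bool


@dataclass
class GLCMConfig:
    levels: int = 32
    distances: tuple[int, ...] = (1,)
    angles: tuple[int, ...] = ANGLES_DEFAULT

    def __post_init__(self) -> None:
        if not (2 <= self.levels <= 256):
            raise ParameterError("levels must lie in [2, 256]")
        if not self.distances or any(d < 1 for d in self.distances):
            raise ParameterError("distances must be positive integers")
        if any(a not in (0, 45, 90, 135) for a in self.angles):
            raise ParameterError("angles must be drawn from {0, 45, 90, 135}")


def quantize(image: Image | np.ndarray, levels: int) -> np.ndarray:
    """Uniform quantization of [0, 255] intensities into ``levels`` bins.

    The mapping floor(v * levels / 256) is monotone; levels = 256 is the
    identity.
    """
    if not (2 <= levels <= 256):
        raise ParameterError("levels must lie in [2, 256]")
    pixels = image.pixels if isinstance(image, Image) else np.asarray(image)
    return (pixels.astype(np.int64) * levels // 256).astype(np.uint8)


def compute_glcm(
    qimage: np.ndarray,
    levels: int,
    distance: int = 1,
    angle: int = 0,
    symmetric: bool = True,
    normalize: bool = True,
) -> GLCM:
    """Count co-occurrences of quantized levels at offset (distance, angle).

    Entry (i, j) counts pairs (reference = i, neighbor = j); ``symmetric`` adds
    the transposed counts, ``normalize`` divides by the total pair count.
    Offsets follow the standard convention with rows growing downward:
    0 deg -> (0, d) right, 45 deg -> (-d, d) up-right, 90 deg -> (-d, 0) up,
    135 deg -> (-d, -d) up-left.
    """
    q = np.asarray(qimage)
    if q.ndim != 2:
        raise ParameterError("quantized image must be 2-D")
    if q.max(initial=0) >= levels:
        raise ParameterError("quantized values exceed the declared level count")
    if angle not in _OFFSETS:
        raise ParameterError("angle must be one of 0, 45, 90, 135 degrees")
    if distance < 1:
        raise ParameterError("distance must be >= 1")
    dr, dc = (o * distance for o in _OFFSETS[angle])
    h, w = q.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise ParameterError(
            f"no valid pixel pairs at distance {distance}, angle {angle} for shape {q.shape}"
        )
    ref = q[r0:r1, c0:c1].ravel().astype(np.intp)
    nbr = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel().astype(np.intp)
    counts = np.zeros((levels, levels))
    np.add.at(counts, (ref, nbr), 1.0)
    if symmetric:
        counts = counts + counts.T
    matrix = counts / counts.sum() if normalize else counts
    return GLCM(matrix, levels, distance, angle, symmetric, normalize)


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _max_correlation_coefficient(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    keep_x, keep_y = px > 0, py > 0
    A = P[np.ix_(keep_x, keep_y)]
    if min(A.shape) < 2:
        return 0.0
    Q = (A / px[keep_x, None]) @ (A / py[None, keep_y]).T
    eig = np.linalg.eigvals(Q)
    eig = np.sort(np.real(eig))[::-1]
    second = float(np.clip(eig[1], 0.0, 1.0))
    return float(np.sqrt(second))


def glcm_feature_set(glcm: GLCM) -> dict[str, float]:
    """All 25 scalar statistics of one normalized GLCM, keyed by FEATURE_NAMES."""
    if not glcm.normalized:
        raise ParameterError("glcm_feature_set requires a normalized GLCM")
    P = glcm.matrix
    L = glcm.levels
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px, py = P.sum(axis=1), P.sum(axis=0)
    mu_x, mu_y = float(i @ px), float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)

    diff = ii - jj
    absdiff = np.abs(diff)
    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    p_sum = np.bincount((ii + jj).astype(int).ravel(), weights=P.ravel(), minlength=2 * L - 1)
    p_diff = np.bincount(absdiff.astype(int).ravel(), weights=P.ravel(), minlength=L)
    k_sum = np.arange(2 * L - 1, dtype=np.float64)
    k_diff = np.arange(L, dtype=np.float64)

    contrast = float((diff**2 * P).sum())
    dissimilarity = float((absdiff * P).sum())
    homogeneity = float((P / (1.0 + diff**2)).sum())
    energy = float((P**2).sum())
    entropy = _entropy(P.ravel())
    cov = float((ii * jj * P).sum()) - mu_x * mu_y
    denom = np.sqrt(var_x * var_y)
    correlation = float(cov / denom) if denom > 0 else 1.0
    variance = float((((ii - mu_x) ** 2) * P).sum())
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy(p_sum)
    diff_mean = float(k_diff @ p_diff)
    difference_variance = float(((k_diff - diff_mean) ** 2) @ p_diff)
    difference_entropy = _entropy(p_diff)

    pxpy = np.outer(px, py)
    mask = pxpy > 0
    hxy1 = float(-(P[mask] * np.log2(pxpy[mask])).sum())
    hxy2 = float(-(pxpy[mask] * np.log2(pxpy[mask])).sum())
    hx, hy = _entropy(px), _entropy(py)
    max_h = max(hx, hy)
    imc1 = float((entropy - hxy1) / max_h) if max_h > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    autocorrelation = float((ii * jj * P).sum())
    cs = ii + jj - mu_x - mu_y
    cluster_shade = float((cs**3 * P).sum())
    cluster_prominence = float((cs**4 * P).sum())
    maximum_probability = float(P.max())
    inverse_difference = float((P / (1.0 + absdiff)).sum())
    idn = float((P / (1.0 + absdiff / L)).sum())
    idmn = float((P / (1.0 + diff**2 / L**2)).sum())
    mcc = _max_correlation_coefficient(P, px, py)

    values = {
        "contrast": contrast,
        "dissimilarity": dissimilarity,
        "homogeneity": homogeneity,
        "energy": energy,
        "entropy": entropy,
        "correlation": correlation,
        "variance": variance,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": imc1,
        "imc2": imc2,
        "autocorrelation": autocorrelation,
        "cluster_shade": cluster_shade,
        "cluster_prominence": cluster_prominence,
        "maximum_probability": maximum_probability,
        "inverse_difference": inverse_difference,
        "inverse_difference_normalized": idn,
        "inverse_difference_moment_normalized": idmn,
        "max_correlation_coefficient": mcc,
        "mean_x": mu_x,
        "mean_y": mu_y,
        "marginal_entropy": hx,
    }
    assert tuple(values) == FEATURE_NAMES
    return values


def static_feature_vector(
    image: Image | np.ndarray, config: GLCMConfig = GLCMConfig()
) -> "pd.Series":
    """The 25-element static texture descriptor of one image.

    Per-matrix features are computed for every configured (distance, angle)
    offset and averaged, which makes the descriptor tolerant to 90-degree
    rotations when the full angle set is used.
    """
    q = quantize(image, config.levels)
    acc = np.zeros(len(FEATURE_NAMES))
    n = 0
    for d in config.distances:
        for a in config.angles:
            feats = glcm_feature_set(compute_glcm(q, config.levels, d, a))
            acc += np.fromiter(feats.values(), dtype=np.float64)
            n += 1
    return pd.Series(acc / n, index=list(FEATURE_NAMES))


def static_feature_table(
    images: Iterable[Image], config: GLCMConfig = GLCMConfig()
) -> pd.DataFrame:
    """Static feature vectors for a collection of images, one row per image.

    Index = image id; columns = the 25 feature names plus the class column.
    """
    rows, ids, labels = [], [], []
    for img in images:
        rows.append(static_feature_vector(img, config))
        ids.append(img.id)
        labels.append(img.label)
    table = pd.DataFrame(rows)
    table.index = pd.Index(ids, name="id")
    table[CLASS_COLUMN] = labels
    return table
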