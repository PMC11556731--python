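"""Shared fixtures and independent oracles used across the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------

# standard offsets (row, col) with rows growing downward; 90 deg points up
GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(q, levels, distance=1, angle=0, symmetric=True, normalize=True):
    """Exhaustive pair enumeration over all pixel positions."""
    q = np.asarray(q)
    dr, dc = GLCM_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = q.shape
    m = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                m[q[r, c], q[r2, c2]] += 1
    if symmetric:
        m = m + m.T
    if normalize:
        total = m.sum()
        if total > 0:
            m = m / total
    return m


def brute_force_mdfs(table: pd.DataFrame, class_col: str = "class"):
    """Literal evaluation of the strict mean-equality set definitions.

    Returns (per_class dict, intersection set).  Independent of the package:
    plain loops over rows and label pairs, exact equality of means.
    """
    features = [c for c in table.columns if c != class_col]
    labels = sorted(set(table[class_col]))
    means = {}
    for y in labels:
        rows = table[table[class_col] == y]
        means[y] = {f: sum(rows[f]) / len(rows) for f in features}
    per_class = {}
    for y in labels:
        keep = []
        for f in features:
            if all(means[y][f] != means[y2][f] for y2 in labels if y2 != y):
                keep.append(f)
        per_class[y] = keep
    intersection = set(features)
    for keep in per_class.values():
        intersection &= set(keep)
    return per_class, intersection


def brute_force_auc(truth, scores, positive):
    """Pairwise concordance: P(random positive outranks random negative)."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    pos = scores[truth == positive]
    neg = scores[truth != positive]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def texture_specs():
    from texfuse import synthetic

    return [
        synthetic.TextureClassSpec(label="fine", smoothing_scale=1.0, size=(32, 32)),
        synthetic.TextureClassSpec(label="medium", smoothing_scale=2.5, size=(32, 32)),
        synthetic.TextureClassSpec(label="coarse", smoothing_scale=6.0, size=(32, 32)),
        synthetic.TextureClassSpec(
            label="checks", family="checker", smoothing_scale=4.0, size=(32, 32)
        ),
    ]


@pytest.fixture
def small_dataset(texture_specs):
    from texfuse import synthetic

    return synthetic.generate_dataset(texture_specs, [6, 6, 6, 6], seed=7)
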