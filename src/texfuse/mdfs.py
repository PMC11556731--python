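"""Mean-dropout feature selection (MDFS).

A filter method over a labelled feature table: compute the class-conditional
mean of every feature, keep for each class only the features whose mean in
that class differs from its mean in every other class, and intersect the
per-class keep-sets.  Features whose class means coincide carry no
first-moment class information and are dropped.

Formally, with X the table, F its feature columns, C the class column and Y
the set of class labels::

    mean[y][f]          = (1 / N_y) * sum over rows x with x[C] = y of x[f]
    selected(y)         = { f in F : |mean[y][f] - mean[y'][f]| > eps_f
                            for every y' != y }
    selected_all        = intersection over y in Y of selected(y)

The strict form uses eps_f = 0 (exact mean equality drops a feature).  On
continuous features exact equality of empirical means is a measure-zero
event, so the filter is generalized with a tolerance: two class means are
considered equal when their difference is within ``tolerance`` times a
per-feature scale.  With ``relative=True`` (default) the scale is
``max(1, pooled within-class sd of f)``; with ``relative=False`` the
tolerance is absolute.  ``tolerance=0`` recovers the strict definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CLASS_COLUMN, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 0.05


def _validate_table(table: pd.DataFrame, class_col: str) -> list[str]:
    if class_col not in table.columns:
        raise ParameterError(f"table lacks the {class_col!r} column")
    features = [c for c in table.columns if c != class_col]
    if not features:
        raise ParameterError("table has no feature columns")
    if len(table) < 1:
        raise ParameterError("table has no rows")
    if table[features].isna().any().any():
        raise ParameterError("feature table contains missing values")
    return features


def class_mean_table(table: pd.DataFrame, class_col: str = CLASS_COLUMN) -> pd.DataFrame:
    """Class-conditional means: rows = class labels, columns = features."""
    features = _validate_table(table, class_col)
    means = table.groupby(class_col, sort=True)[features].mean()
    means.index.name = class_col
    return means


def pooled_within_class_sd(
    table: pd.DataFrame, class_col: str = CLASS_COLUMN
) -> pd.Series:
    """Pooled within-class standard deviation of every feature.

    sqrt( sum_y (N_y - 1) s_y^2 / (N - K) ); zero when every class has a
    single row.
    """
    features = _validate_table(table, class_col)
    grouped = table.groupby(class_col, sort=True)[features]
    counts = grouped.size()
    n, k = int(counts.sum()), len(counts)
    if n <= k:
        return pd.Series(0.0, index=features)
    var = grouped.var(ddof=1).fillna(0.0)
    pooled = ((counts - 1).to_numpy()[:, None] * var.to_numpy()).sum(axis=0) / (n - k)
    return pd.Series(np.sqrt(pooled), index=features)


def _thresholds(
    means: pd.DataFrame, tolerance: float, relative: bool, scale: pd.Series | None
) -> pd.Series:
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    if not relative or scale is None:
        return pd.Series(float(tolerance), index=means.columns)
    return pd.Series(
        tolerance * np.maximum(1.0, scale.reindex(means.columns).to_numpy()),
        index=means.columns,
    )


def select_per_class(
    means: pd.DataFrame,
    y: str,
    tolerance: float = 0.0,
    relative: bool = False,
    scale: pd.Series | None = None,
) -> list[str]:
    """Features whose class-``y`` mean differs from every other class's mean.

    ``means`` is a class-by-feature table (see :func:`class_mean_table`).
    A difference counts only when it exceeds the per-feature threshold
    (``tolerance`` times the feature scale under ``relative``).  With a single
    class in the table the condition quantifies over an empty set and every
    feature is (vacuously) selected.
    """
    if y not in means.index:
        raise ParameterError(f"unknown class label {y!r}")
    thr = _thresholds(means, tolerance, relative, scale)
    others = means.drop(index=y)
    if others.empty:
        return list(means.columns)
    gaps = (others - means.loc[y]).abs()
    keep = (gaps > thr).all(axis=0)
    return [f for f in means.columns if keep[f]]


@dataclass
class SelectionResult:
    """Outcome of MDFS: per-class keep-sets and their intersection."""

    per_class: dict[str, list[str]]
    intersection: list[str]
    dropped: list[str]
    tolerance: float
    relative: bool
    means: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "tolerance": self.tolerance,
            "relative": self.relative,
            "per_class": self.per_class,
            "intersection": self.intersection,
            "dropped": self.dropped,
            "class_means": {
                y: {f: float(v) for f, v in row.items()}
                for y, row in self.means.iterrows()
            },
        }


def mdfs_select(
    table: pd.DataFrame,
    tolerance: float = DEFAULT_TOLERANCE,
    relative: bool = True,
    class_col: str = CLASS_COLUMN,
) -> SelectionResult:
    """Run mean-dropout selection on a labelled feature table.

    Returns the per-class keep-sets, their intersection (in the table's
    column order) and the dropped complement.  The result is invariant to row
    order and to feature-column order (as sets), and selection at a larger
    tolerance is always a subset of selection at a smaller one.
    """
    features = _validate_table(table, class_col)
    means = class_mean_table(table, class_col)
    scale = pooled_within_class_sd(table, class_col) if relative else None
    if len(means.index) < 2:
        logger.warning(
            "MDFS on a single-class table: selection is vacuous, keeping all %d features",
            len(features),
        )
    per_class = {
        y: select_per_class(means, y, tolerance, relative, scale) for y in means.index
    }
    kept = set(features)
    for sel in per_class.values():
        kept &= set(sel)
    intersection = [f for f in features if f in kept]
    dropped = [f for f in features if f not in kept]
    return SelectionResult(per_class, intersection, dropped, float(tolerance), relative, means)


def apply_selection(
    table: pd.DataFrame, result: SelectionResult, class_col: str = CLASS_COLUMN
) -> pd.DataFrame:
    """Restrict a table to the selected features plus the class column."""
    features = _validate_table(table, class_col)
    missing = [f for f in result.intersection if f not in features]
    if missing:
        raise ParameterError(f"selection references features absent from table: {missing}")
    if not result.intersection:
        logger.warning("selection intersection is empty: table reduced to the class column")
    return table[result.intersection + [class_col]]
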