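"""Hybrid feature fusion, gradient-boosted training and evaluation surfaces.

Static (GLCM) and dynamic (deep) feature tables are fused column-wise into a
hybrid feature space; a gradient-boosted tree ensemble (XGBoost) is selected
by exhaustive grid search scored with inner stratified cross-validation and
refit on the full training partition.  Evaluation produces a confusion
matrix, per-class precision/recall/F1/support with macro and weighted
averages, one-vs-rest ROC AUC per class, and stratified k-fold
cross-validation in which feature selection is refit inside every training
partition (never on held-out rows).
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from . import mdfs
from .types import CLASS_COLUMN, ParameterError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature fusion
# ---------------------------------------------------------------------------

def fuse_features(static: pd.DataFrame, dynamic: pd.DataFrame) -> pd.DataFrame:
    """Column-wise concatenation of two feature tables on shared sample ids.

    Both tables must carry the same index (sample ids) and identical class
    labels; the fused table holds the static columns, then the dynamic
    columns, then the class column.
    """
    for name, t in (("static", static), ("dynamic", dynamic)):
        if CLASS_COLUMN not in t.columns:
            raise ParameterError(f"{name} table lacks the {CLASS_COLUMN!r} column")
    if len(static) != len(dynamic) or set(static.index) != set(dynamic.index):
        offending = sorted(set(static.index) ^ set(dynamic.index))
        raise ParameterError(f"sample id mismatch between tables: {offending[:10]}")
    dynamic = dynamic.loc[static.index]
    if not (static[CLASS_COLUMN].to_numpy() == dynamic[CLASS_COLUMN].to_numpy()).all():
        raise ParameterError("class labels disagree between static and dynamic tables")
    overlap = (set(static.columns) & set(dynamic.columns)) - {CLASS_COLUMN}
    if overlap:
        raise ParameterError(f"duplicate feature names across tables: {sorted(overlap)}")
    fused = pd.concat(
        [static.drop(columns=CLASS_COLUMN), dynamic.drop(columns=CLASS_COLUMN)], axis=1
    )
    fused[CLASS_COLUMN] = static[CLASS_COLUMN]
    return fused


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    test_fraction: float = 0.2
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ParameterError("test_fraction must lie strictly between 0 and 1")


def _apportion_test_counts(counts: pd.Series, fraction: float) -> dict[str, int]:
    """Largest-remainder apportionment of the test fraction across classes.

    Total test size is round(N * fraction); each class gets floor(N_y *
    fraction) rows, and remaining seats go to the largest fractional
    remainders (ties broken by class-name order).
    """
    quotas = counts * fraction
    base = np.floor(quotas).astype(int)
    total = int(np.floor(counts.sum() * fraction + 0.5))
    seats = total - int(base.sum())
    remainders = sorted(
        ((float(quotas[y] - base[y]), y) for y in counts.index),
        key=lambda t: (-t[0], t[1]),
    )
    out = {y: int(base[y]) for y in counts.index}
    for _, y in remainders[: max(0, seats)]:
        out[y] += 1
    return out


def stratified_split(
    table: pd.DataFrame, spec: SplitSpec = SplitSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-stratified train/test split; reproducible from the seed."""
    if CLASS_COLUMN not in table.columns:
        raise ParameterError(f"table lacks the {CLASS_COLUMN!r} column")
    counts = table[CLASS_COLUMN].value_counts().sort_index()
    if (counts < 2).any():
        bad = list(counts.index[counts < 2])
        raise ParameterError(f"every class needs >= 2 rows for a split; offending: {bad}")
    test_counts = _apportion_test_counts(counts, spec.test_fraction)
    rng = np.random.default_rng(spec.seed)
    test_mask = np.zeros(len(table), dtype=bool)
    labels = table[CLASS_COLUMN].to_numpy()
    for y in counts.index:
        rows = np.flatnonzero(labels == y)
        picked = rng.choice(rows, size=test_counts[y], replace=False)
        test_mask[picked] = True
    return table.loc[~test_mask], table.loc[test_mask]


# ---------------------------------------------------------------------------
# model selection and fitting
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Hyperparameter grid for the gradient-boosted classifier."""

    booster: tuple = ("gbtree", "gblinear")
    colsample_bytree: tuple = (0.4, 0.6, 0.8, 1)
    learning_rate: tuple = (0.01, 0.1, 0.2, 0.4)
    max_depth: tuple = (2, 3, 4, 6)
    n_estimators: tuple = (200, 300, 400, 500)
    subsample: tuple = (0.4, 0.6, 0.8, 1)

    def __post_init__(self) -> None:
        for name in ("booster", "colsample_bytree", "learning_rate",
                     "max_depth", "n_estimators", "subsample"):
            if not getattr(self, name):
                raise ParameterError(f"grid axis {name!r} must be non-empty")

    def combinations(self) -> list[dict]:
        """All grid points in listed (row-major) order; ties break by this order."""
        keys = ("booster", "colsample_bytree", "learning_rate",
                "max_depth", "n_estimators", "subsample")
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(getattr(self, k) for k in keys))
        ]


def tuned_params() -> dict:
    """The single tuned grid point used as the pipeline default."""
    return {
        "booster": "gbtree",
        "colsample_bytree": 1,
        "learning_rate": 0.1,
        "max_depth": 6,
        "n_estimators": 200,
        "subsample": 0.8,
    }


@dataclass
class FittedModel:
    booster: XGBClassifier
    classes: np.ndarray
    features: list[str]
    params: dict


def _split_xy(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    features = [c for c in table.columns if c != CLASS_COLUMN]
    if not features:
        raise ParameterError("table has no feature columns")
    return table[features], table[CLASS_COLUMN].to_numpy()


def _make_classifier(params: dict, n_classes: int, seed: int) -> XGBClassifier:
    # softmax probabilities for K > 2; the two-class case uses the logistic
    # objective (multi:softprob rejects binary targets)
    objective = "multi:softprob" if n_classes > 2 else "binary:logistic"
    return XGBClassifier(
        objective=objective,
        n_jobs=1,
        random_state=seed,
        verbosity=0,
        **params,
    )


def fit_model(train: pd.DataFrame, params: dict, seed: int = 0) -> FittedModel:
    """Fit the boosted classifier with fixed hyperparameters."""
    X, y = _split_xy(train)
    classes = np.array(sorted(pd.unique(y)))
    if len(classes) < 2:
        raise ParameterError("training table must contain at least 2 classes")
    codes = np.searchsorted(classes, y)
    clf = _make_classifier(params, len(classes), seed)
    clf.fit(X.to_numpy(), codes)
    return FittedModel(clf, classes, list(X.columns), dict(params))


def grid_search_train(
    train: pd.DataFrame,
    grid: GridSpec = GridSpec(),
    inner_folds: int = 3,
    seed: int = 0,
) -> tuple[FittedModel, dict]:
    """Exhaustive grid search scored by inner stratified-CV accuracy.

    Ties break by grid order (the first best combination wins); the winning
    parameters are refit on the full training table.
    """
    X, y = _split_xy(train)
    classes = np.array(sorted(pd.unique(y)))
    if len(classes) < 2:
        raise ParameterError("training table must contain at least 2 classes")
    codes = np.searchsorted(classes, y)
    combos = grid.combinations()
    best_params, best_score = None, -np.inf
    if len(combos) == 1:
        best_params = combos[0]
    else:
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, codes))
        Xa = X.to_numpy()
        for params in combos:
            accs = []
            for tr, va in folds:
                clf = _make_classifier(params, len(classes), seed)
                clf.fit(Xa[tr], codes[tr])
                accs.append(float((clf.predict(Xa[va]) == codes[va]).mean()))
            score = float(np.mean(accs))
            if score > best_score:
                best_params, best_score = params, score
    model = fit_model(train, best_params, seed)
    logger.info("grid search selected %s (inner-CV accuracy %.4f)", best_params, best_score)
    return model, best_params


def predict(model: FittedModel, table: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Predicted labels and class-probability rows (summing to 1) for a table."""
    features = [c for c in table.columns if c != CLASS_COLUMN]
    if features != model.features:
        missing = sorted(set(model.features) - set(features))
        extra = sorted(set(features) - set(model.features))
        raise ParameterError(
            f"feature columns do not match training columns "
            f"(missing {missing[:5]}, unexpected {extra[:5]})"
        )
    proba = model.booster.predict_proba(table[features].to_numpy())
    labels = model.classes[np.argmax(proba, axis=1)]
    return labels, pd.DataFrame(proba, columns=model.classes, index=table.index)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    labels: list[str]
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    accuracy: float
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    per_class_auc: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "accuracy": self.accuracy,
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
            "per_class_auc": self.per_class_auc,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def roc_auc_ovr(truth, scores: pd.DataFrame, positive: str) -> float:
    """One-vs-rest AUC: probability a random positive outranks a random
    negative, ties counted half."""
    truth = np.asarray(truth)
    if positive not in scores.columns:
        raise ParameterError(f"no score column for class {positive!r}")
    binary = (truth == positive).astype(int)
    if binary.min() == binary.max():
        raise ParameterError(
            f"AUC undefined: class {positive!r} is absent or exhaustive in truth"
        )
    return float(roc_auc_score(binary, scores[positive].to_numpy()))


def classification_report(
    truth, predicted, scores: pd.DataFrame | None = None
) -> EvalReport:
    """Confusion matrix, per-class P/R/F1/support, averages and OVR AUC.

    Per class: P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 cases are
    reported as 0 with a warning.  Macro averages are unweighted means;
    weighted averages are support-weighted means.  AUC is included per class
    when probability scores are supplied.
    """
    truth, predicted = np.asarray(truth), np.asarray(predicted)
    if len(truth) != len(predicted):
        raise ParameterError("truth and predicted must have equal lengths")
    labels = sorted(set(truth) | set(predicted))
    conf = confusion_matrix(truth, predicted, labels=labels)
    per_class: dict[str, dict[str, float]] = {}
    for i, y in enumerate(labels):
        tp = float(conf[i, i])
        fp = float(conf[:, i].sum() - tp)
        fn = float(conf[i].sum() - tp)
        if tp + fp == 0:
            warnings.warn(f"class {y!r} has no predicted positives; precision set to 0")
            p = 0.0
        else:
            p = tp / (tp + fp)
        if tp + fn == 0:
            warnings.warn(f"class {y!r} has no true positives in truth; recall set to 0")
            r = 0.0
        else:
            r = tp / (tp + fn)
        f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        per_class[y] = {
            "precision": p, "recall": r, "f1": f1, "support": int(conf[i].sum())
        }
    total = int(conf.sum())
    accuracy = float(np.trace(conf) / total) if total else 0.0
    supports = np.array([per_class[y]["support"] for y in labels], dtype=float)
    macro, weighted = {}, {}
    for metric in ("precision", "recall", "f1"):
        vals = np.array([per_class[y][metric] for y in labels])
        macro[metric] = float(vals.mean())
        weighted[metric] = float((vals * supports).sum() / supports.sum()) if total else 0.0
    auc: dict[str, float] = {}
    if scores is not None:
        for y in labels:
            present = (truth == y).any() and not (truth == y).all()
            if present and y in scores.columns:
                auc[y] = roc_auc_ovr(truth, scores, y)
    return EvalReport(labels, conf, per_class, accuracy, macro, weighted, auc)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    accuracies: list[float]
    mean: float
    sd: float
    k: int
    seed: int

    def to_dict(self) -> dict:
        return {"accuracies": self.accuracies, "mean": self.mean,
                "sd": self.sd, "k": self.k, "seed": self.seed}


def kfold_cv(
    table: pd.DataFrame,
    k: int,
    params: dict | None = None,
    grid: GridSpec | None = None,
    inner_folds: int = 3,
    tolerance: float = mdfs.DEFAULT_TOLERANCE,
    relative: bool = True,
    select: bool = True,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold accuracy of the selection + boosting pipeline.

    Feature selection is refit on each fold's training partition only, so no
    held-out information leaks into the selected set.  ``params`` fixes the
    booster hyperparameters; pass ``grid`` instead to grid-search within each
    fold.
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    X, y = _split_xy(table)
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        raise ParameterError(f"k={k} exceeds the smallest class count {int(counts.min())}")
    if params is None and grid is None:
        params = tuned_params()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        train, test = table.iloc[tr], table.iloc[te]
        if select:
            sel = mdfs.mdfs_select(train, tolerance=tolerance, relative=relative)
            train = mdfs.apply_selection(train, sel)
            test = mdfs.apply_selection(test, sel)
        if grid is not None:
            model, _ = grid_search_train(train, grid, inner_folds, seed)
        else:
            model = fit_model(train, params, seed)
        pred, _ = predict(model, test)
        accs.append(float((pred == test[CLASS_COLUMN].to_numpy()).mean()))
    return CVReport(accs, float(np.mean(accs)), float(np.std(accs)), k, seed)


# ---------------------------------------------------------------------------
# model export
# ---------------------------------------------------------------------------

def export_model(
    model: FittedModel,
    selection: mdfs.SelectionResult | None,
    path,
    preprocess_config=None,
    glcm_config=None,
) -> int:
    """Serialize the model bundle; returns its size in bytes.

    The bundle carries the fitted booster, the selected feature names and the
    preprocessing/GLCM configuration needed to reproduce predictions exactly
    on reload.
    """
    path = Path(path)
    bundle = {
        "model": model,
        "selection": None if selection is None else selection.to_dict(),
        "preprocess_config": preprocess_config,
        "glcm_config": glcm_config,
    }
    try:
        joblib.dump(bundle, path, compress=3)
    except OSError as exc:
        raise IOError(f"cannot write model bundle to {path}: {exc}") from exc
    size = path.stat().st_size
    logger.info("model bundle written to %s (%d bytes)", path, size)
    return size


def load_model(path) -> dict:
    """Reload an exported bundle (inverse of :func:`export_model`)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"model bundle {path} not found")
    return joblib.load(path)
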