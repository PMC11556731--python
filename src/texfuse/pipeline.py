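"""End-to-end pipeline orchestration: config schema, manifest ingestion, run.

A :class:`PipelineConfig` (pydantic schema; unknown keys rejected) describes a
full run: data source (synthetic texture classes or an on-disk image
manifest), preprocessing, balancing, GLCM and deep feature extraction,
mean-dropout selection, training and evaluation.  :func:`run_pipeline`
executes the stages in order and writes every intermediate artifact plus the
resolved config into a run directory, so a run is reproducible from that
directory alone.  A single global seed deterministically derives per-stage
seeds by hashing the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import augment, classify, deep, glcm, mdfs, preprocess, synthetic
from .types import CLASS_COLUMN, Dataset, Image, ParameterError, to_grayscale_u8

logger = logging.getLogger(__name__)

_IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by stage-name hashing."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# config schema
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticClassConfig(_Strict):
    label: str
    family: Literal["smoothed-noise", "checker", "blob"] = "smoothed-noise"
    smoothing_scale: float = 2.0
    amplitude: float = 120.0
    noise_sd: float = 8.0
    count: int = 50


class DataConfig(_Strict):
    source: Literal["synthetic", "manifest"] = "synthetic"
    manifest: Optional[str] = None
    image_size: tuple[int, int] = (64, 64)
    classes: list[SyntheticClassConfig] = Field(
        default_factory=lambda: [
            SyntheticClassConfig(label="classA", smoothing_scale=1.0),
            SyntheticClassConfig(label="classB", smoothing_scale=2.5),
            SyntheticClassConfig(label="classC", smoothing_scale=6.0),
            SyntheticClassConfig(label="classD", family="checker", smoothing_scale=4.0),
        ]
    )


class PreprocessSection(_Strict):
    out_size: tuple[int, int] = (64, 64)
    median_kernel: int = 3
    equalize: bool = True

    @field_validator("median_kernel")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v < 1 or v % 2 == 0:
            raise ValueError("median_kernel must be an odd integer >= 1")
        return v


class AugmentSection(_Strict):
    balance: bool = True


class GLCMSection(_Strict):
    levels: int = 32
    distances: tuple[int, ...] = (1,)
    angles: tuple[int, ...] = (0, 45, 90, 135)


class DeepSection(_Strict):
    enabled: bool = True
    topology: str = "random_projection"
    output_dim: int = 64
    weights_seed: Optional[int] = None  # default: derived from the global seed


class MDFSSection(_Strict):
    tolerance: float = mdfs.DEFAULT_TOLERANCE
    relative: bool = True

    @field_validator("tolerance")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("tolerance must be >= 0")
        return v


class TrainSection(_Strict):
    grid: dict[str, list] = Field(
        default_factory=lambda: {k: [v] for k, v in classify.tuned_params().items()}
    )
    inner_folds: int = 3


class EvalSection(_Strict):
    test_fraction: float = 0.2

    @field_validator("test_fraction")
    @classmethod
    def _frac(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError("test_fraction must lie strictly between 0 and 1")
        return v


class PipelineConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs"
    run_name: Optional[str] = None  # default: timestamped
    data: DataConfig = Field(default_factory=DataConfig)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    augment: AugmentSection = Field(default_factory=AugmentSection)
    glcm: GLCMSection = Field(default_factory=GLCMSection)
    deep: DeepSection = Field(default_factory=DeepSection)
    mdfs: MDFSSection = Field(default_factory=MDFSSection)
    train: TrainSection = Field(default_factory=TrainSection)
    eval: EvalSection = Field(default_factory=EvalSection)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def _read_image(path: Path, label: str) -> Image:
    try:
        pixels = iio.imread(path)
    except Exception as exc:
        raise IOError(f"unreadable image file {path}: {exc}") from exc
    return Image(pixels=to_grayscale_u8(pixels), label=label, id=path.stem)


def ingest_manifest(path) -> Dataset:
    """Load a dataset from a manifest CSV (path,label) or a class-per-directory tree."""
    path = Path(path)
    images: list[Image] = []
    if path.is_file():
        manifest = pd.read_csv(path)
        if not {"path", "label"} <= set(manifest.columns):
            raise ParameterError("manifest CSV needs 'path' and 'label' columns")
        for _, row in manifest.iterrows():
            img_path = Path(row["path"])
            if not img_path.is_absolute():
                img_path = path.parent / img_path
            if not img_path.exists():
                raise IOError(f"manifest references missing file {img_path}")
            images.append(_read_image(img_path, str(row["label"])))
    elif path.is_dir():
        for class_dir in sorted(p for p in path.iterdir() if p.is_dir()):
            for img_path in sorted(class_dir.iterdir()):
                if img_path.suffix.lower() not in _IMAGE_EXTS:
                    logger.warning("skipping non-image file %s", img_path)
                    continue
                images.append(_read_image(img_path, class_dir.name))
    else:
        raise IOError(f"no such manifest or directory: {path}")
    if not images:
        raise ParameterError(f"no images found under {path}")
    ds = Dataset(images=images)
    logger.info("ingested %d images; class census: %s", len(ds), ds.class_counts)
    return ds


def write_dataset(dataset: Dataset, out_dir) -> Path:
    """Write a dataset as class-per-directory PNGs plus a manifest CSV."""
    out_dir = Path(out_dir)
    rows = []
    for img in dataset:
        class_dir = out_dir / (img.label or "unlabelled")
        class_dir.mkdir(parents=True, exist_ok=True)
        img_path = class_dir / f"{img.id}.png"
        iio.imwrite(img_path, img.pixels)
        rows.append({"path": str(img_path.relative_to(out_dir)), "label": img.label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# run
# ---------------------------------------------------------------------------

def _build_dataset(config: PipelineConfig) -> Dataset:
    if config.data.source == "manifest":
        if not config.data.manifest:
            raise ParameterError("data.source='manifest' requires data.manifest")
        return ingest_manifest(config.data.manifest)
    specs = [
        synthetic.TextureClassSpec(
            label=c.label, family=c.family, smoothing_scale=c.smoothing_scale,
            amplitude=c.amplitude, noise_sd=c.noise_sd, size=config.data.image_size,
        )
        for c in config.data.classes
    ]
    counts = {c.label: c.count for c in config.data.classes}
    return synthetic.generate_dataset(specs, counts, stage_seed(config.seed, "simulate"))


def _build_extractor(config: PipelineConfig) -> deep.Extractor:
    seed = config.deep.weights_seed
    if seed is None:
        seed = stage_seed(config.seed, "deep")
    spec = deep.ExtractorSpec(
        topology=config.deep.topology,
        output_dim=config.deep.output_dim,
        weights=("random", seed),
        input_size=tuple(config.preprocess.out_size),
    )
    return deep.build_extractor(spec)


def run_pipeline(config: PipelineConfig, run_dir=None) -> Path:
    """Execute the full pipeline and write all artifacts to a run directory.

    Stages: simulate/ingest -> preprocess -> balance -> static features ->
    deep features -> fuse -> stratified split -> selection (fit on train
    only) -> train -> evaluate -> export.  Returns the run directory.
    """
    if run_dir is None:
        name = config.run_name or time.strftime("run-%Y%m%d-%H%M%S")
        run_dir = Path(config.out_dir) / name
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config_resolved.yaml").write_text(
        yaml.safe_dump(json.loads(config.model_dump_json()), sort_keys=True)
    )

    stage = "ingest"
    try:
        dataset = _build_dataset(config)

        stage = "preprocess"
        pcfg = preprocess.PreprocessConfig(
            out_size=tuple(config.preprocess.out_size),
            median_kernel=config.preprocess.median_kernel,
            equalize=config.preprocess.equalize,
        )
        dataset = Dataset(images=[preprocess.preprocess_pipeline(im, pcfg) for im in dataset])

        stage = "balance"
        if config.augment.balance:
            dataset = augment.balance_classes(
                dataset, seed=stage_seed(config.seed, "balance")
            )
        logger.info("class census entering feature extraction: %s", dataset.class_counts)

        stage = "static_features"
        gcfg = glcm.GLCMConfig(
            levels=config.glcm.levels,
            distances=tuple(config.glcm.distances),
            angles=tuple(config.glcm.angles),
        )
        static = glcm.static_feature_table(dataset, gcfg)
        static.to_csv(run_dir / "static_features.csv")

        stage = "deep_features"
        if config.deep.enabled:
            extractor = _build_extractor(config)
            dynamic = deep.extract(extractor, dataset)
            dynamic.to_csv(run_dir / "deep_features.csv")
            stage = "fuse"
            hybrid = classify.fuse_features(static, dynamic)
        else:
            hybrid = static
        hybrid.to_csv(run_dir / "hybrid_features.csv")

        stage = "split"
        train, test = classify.stratified_split(
            hybrid,
            classify.SplitSpec(
                test_fraction=config.eval.test_fraction,
                seed=stage_seed(config.seed, "split"),
            ),
        )

        stage = "select"
        selection = mdfs.mdfs_select(
            train, tolerance=config.mdfs.tolerance, relative=config.mdfs.relative
        )
        logger.info(
            "mean-dropout selection kept %d of %d features",
            len(selection.intersection), len(selection.intersection) + len(selection.dropped),
        )
        (run_dir / "selection.json").write_text(
            json.dumps(selection.to_dict(), sort_keys=True, indent=2)
        )
        train_sel = mdfs.apply_selection(train, selection)
        test_sel = mdfs.apply_selection(test, selection)

        stage = "train"
        grid = classify.GridSpec(**{k: tuple(v) for k, v in config.train.grid.items()})
        model, best_params = classify.grid_search_train(
            train_sel, grid, config.train.inner_folds, stage_seed(config.seed, "train")
        )
        (run_dir / "best_params.json").write_text(json.dumps(best_params, sort_keys=True))

        stage = "evaluate"
        pred, scores = classify.predict(model, test_sel)
        report = classify.classification_report(
            test_sel[CLASS_COLUMN].to_numpy(), pred, scores
        )
        (run_dir / "eval_report.json").write_text(report.to_json())
        pd.DataFrame(
            report.confusion, index=report.labels, columns=report.labels
        ).to_csv(run_dir / "confusion.csv")
        _write_roc_points(test_sel[CLASS_COLUMN].to_numpy(), scores, run_dir / "roc_points.csv")

        stage = "export"
        classify.export_model(model, selection, run_dir / "model_bundle.joblib",
                              preprocess_config=pcfg, glcm_config=gcfg)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("run complete: %s (test accuracy %.4f)", run_dir, report.accuracy)
    return run_dir


def _write_roc_points(truth: np.ndarray, scores: pd.DataFrame, path: Path) -> None:
    from sklearn.metrics import roc_curve

    rows = []
    for y in scores.columns:
        binary = (truth == y).astype(int)
        if binary.min() == binary.max():
            continue
        fpr, tpr, thr = roc_curve(binary, scores[y].to_numpy())
        for f, t, th in zip(fpr, tpr, thr):
            rows.append({"class": y, "fpr": float(f), "tpr": float(t),
                         "threshold": float(th)})
    pd.DataFrame(rows).to_csv(path, index=False)
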