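"""End-to-end orchestration: config, feature extraction, training, reports.

This is the library layer behind the command-line interface. The processing
chain for one sample pair is

    denoise -> frame-difference segmentation -> mask cleanup ->
    color fractions + local entropy + pattern-weighted area +
    a*b* k-means clusters -> feature vector ->
    maturity / health / disease decisions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import classify, features, imaging, synthgen
from .classify import (
    DiseaseLabel,
    FeatureVector,
    HealthLabel,
    TaskModel,
    FEATURE_NAMES,
)
from .exceptions import DataError, EmptyRegionError
from .features import ClusterSet
from .imaging import SegmentedSample

__all__ = [
    "PipelineConfig",
    "Report",
    "extract_sample_features",
    "extract_manifest_features",
    "train_models",
    "analyze_pair",
    "evaluate",
    "health_holdout_accuracy",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "tomatovision.report/1"


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable knobs of the pipeline; serializable to/from YAML.

    The config digest (first 12 hex chars of the SHA-256 of the canonical
    JSON form) is embedded in every report so results are traceable to the
    exact configuration.
    """

    denoise_rank: int = 5
    denoise_window: int = 3
    denoise_background: bool = False  # the empty-chamber frame is clean
    segmentation_threshold: float = 30.0
    min_component_area: int = 64
    mask_erosion_px: int = 3  # strips blur-blended boundary pixels
    entropy_window: int = 9
    entropy_levels: int = 256
    n_clusters: int = 4
    cluster_channels: str = "ab"
    cluster_seed: int = 0
    classifier: str = "knn"  # {knn, lda, qda, pca+knn}
    knn_k: int = 5

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass(frozen=True)
class Report:
    """Per-sample analysis report; every field populated or explicitly None."""

    sample_id: str
    config_digest: str
    red_pct: float | None
    green_pct: float | None
    blue_pct: float | None
    min_entropy: float | None
    max_entropy: float | None
    texture_coefficient: float | None
    area: float | None
    clusters: list | None
    maturity: str | None
    health: str | None
    disease: str | None
    scores: dict | None = None  # per-task per-class classifier scores
    diagnostics: list = field(default_factory=list)
    timestamp: str | None = None  # off by default: reports are deterministic

    def to_json(self) -> str:
        payload = {"schema": REPORT_SCHEMA_VERSION, **asdict(self)}
        return json.dumps(payload, sort_keys=True, indent=1)


def extract_sample_features(
    background: np.ndarray,
    sample: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    sample_id: str = "sample",
) -> tuple[FeatureVector, ClusterSet, SegmentedSample]:
    """Run preprocessing + feature extraction on one frame pair.

    Raises :class:`EmptyRegionError` when segmentation finds no foreground.
    """
    den_sample = imaging.denoise_rank_order(
        sample, rank=config.denoise_rank, window=config.denoise_window
    )
    den_background = (
        imaging.denoise_rank_order(
            background, rank=config.denoise_rank, window=config.denoise_window
        )
        if config.denoise_background
        else background
    )
    seg = imaging.segment_frame_difference(
        den_background, den_sample, threshold=config.segmentation_threshold
    )
    mask = imaging.postprocess_mask(seg.mask, config.min_component_area)
    if not mask.pixels.any():
        raise EmptyRegionError(f"no foreground found in {sample_id}")
    if config.mask_erosion_px > 0:
        # drop boundary pixels blended with the background by camera blur;
        # skipped if erosion would wipe out a tiny foreground
        eroded = ndimage.binary_erosion(
            mask.pixels, iterations=config.mask_erosion_px
        )
        if eroded.any():
            mask = imaging.ForegroundMask(eroded, mask.threshold)
    seg = SegmentedSample(
        image=np.where(mask.pixels[..., None], den_sample, 0), mask=mask
    )

    fractions = features.extract_color_fractions(seg)
    texture = features.texture_entropy(
        seg, window=config.entropy_window, levels=config.entropy_levels
    )
    gray = features.to_grayscale(seg.image)
    binary = imaging.binarize(gray, method="otsu")
    area = features.estimate_area(binary)
    clusters = features.extract_clusters(
        seg,
        k=config.n_clusters,
        seed=config.cluster_seed,
        channels=config.cluster_channels,
    )

    fg_count = int(mask.pixels.sum())
    # per-cluster contrast = shading-robust distance from the base cluster's
    # illumination arc, sorted so feature slots are comparable across samples
    distances = features.cluster_shading_distances(clusters)
    order = np.argsort(-distances, kind="stable")
    cluster_feats = []
    for j in order:
        d = clusters.descriptors[j]
        cluster_feats.extend([distances[j], d.count / fg_count])
    disease_feats = features.lesion_descriptors(clusters, seg)

    values = np.concatenate(
        [
            np.array(
                [
                    fractions.red_pct,
                    fractions.green_pct,
                    fractions.blue_pct,
                    texture.min_entropy,
                    texture.max_entropy,
                    texture.texture_quality_coefficient,
                    area.area,
                ]
            ),
            np.array(cluster_feats),
            disease_feats,
        ]
    )
    return FeatureVector(sample_id=sample_id, values=values), clusters, seg


def extract_manifest_features(
    manifest: pd.DataFrame,
    data_dir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """Feature table (one row per manifest sample) with ground-truth labels."""
    data_dir = Path(data_dir)
    rows = []
    for rec in manifest.itertuples():
        background = imaging.read_image(data_dir / rec.background_path)
        sample = imaging.read_image(data_dir / rec.sample_path)
        fv, _, _ = extract_sample_features(
            background, sample, config, sample_id=rec.sample_id
        )
        row = {"sample_id": rec.sample_id}
        row.update(dict(zip(FEATURE_NAMES, fv.values)))
        row["maturity_label"] = rec.maturity_label
        row["health_label"] = rec.health_label
        row["disease_label"] = rec.disease_label
        rows.append(row)
    return pd.DataFrame(rows)


def _feature_matrix(table: pd.DataFrame) -> np.ndarray:
    return table[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)


def train_models(
    feature_table: pd.DataFrame, config: PipelineConfig = PipelineConfig()
) -> dict[str, TaskModel]:
    """Fit maturity, health, and (where possible) disease task models.

    The disease model trains on infected samples only; it is omitted (with
    no error) when fewer than two archetypes are present.
    """
    X = _feature_matrix(feature_table)
    models: dict[str, TaskModel] = {}
    for task, label_col in (("maturity", "maturity_label"), ("health", "health_label")):
        y = feature_table[label_col].to_numpy()
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise DataError(
                f"{task} training needs >= 2 classes, got {classes!r}"
            )
        if counts.min() < 2:
            sparse = classes[counts < 2]
            raise DataError(
                f"{task} training needs >= 2 samples per class; "
                f"class(es) {sparse.tolist()!r} have fewer"
            )
        models[task] = classify.fit_task_model(
            X, y, task=task, classifier=config.classifier, knn_k=config.knn_k
        )
    infected = feature_table["health_label"] == HealthLabel.RISKY.value
    y_dis = feature_table.loc[infected, "disease_label"].to_numpy()
    if np.unique(y_dis).size >= 2:
        models["disease"] = classify.fit_task_model(
            X[infected.to_numpy()],
            y_dis,
            task="disease",
            classifier=config.classifier,
            knn_k=config.knn_k,
        )
    return models


def analyze_pair(
    background: np.ndarray,
    sample: np.ndarray,
    models: dict[str, TaskModel],
    config: PipelineConfig = PipelineConfig(),
    sample_id: str = "sample",
) -> Report:
    """Full analysis of one frame pair, degrading gracefully on empty input."""
    try:
        fv, clusters, seg = extract_sample_features(
            background, sample, config, sample_id
        )
    except EmptyRegionError as exc:
        return Report(
            sample_id=sample_id,
            config_digest=config.digest(),
            red_pct=None, green_pct=None, blue_pct=None,
            min_entropy=None, max_entropy=None, texture_coefficient=None,
            area=None, clusters=None, maturity=None, health=None, disease=None,
            diagnostics=[f"empty foreground: {exc}"],
        )
    maturity = classify.assess_maturity(fv, models["maturity"])
    health = classify.classify_health(fv, models["health"])
    if health == HealthLabel.RISKY and "disease" in models:
        disease = classify.classify_disease(clusters, fv, models["disease"], health)
    else:
        disease = DiseaseLabel.NONE
    scores = {
        task: {
            label: round(value, 6)
            for label, value in classify.task_scores(
                models[task], fv.values[None, :]
            )[0].items()
        }
        for task in ("maturity", "health", "disease")
        if task in models
    }
    cluster_summaries = [
        {
            "count": d.count,
            "mean_lab": [round(v, 4) for v in d.mean_lab],
            "mean_rgb": [round(v, 4) for v in d.mean_rgb],
            "area": round(d.area, 4),
            "bbox": list(d.bbox),
            "contrast": round(d.contrast, 4),
        }
        for d in clusters.descriptors
    ]
    v = fv.values
    return Report(
        sample_id=sample_id,
        config_digest=config.digest(),
        red_pct=round(float(v[0]), 6),
        green_pct=round(float(v[1]), 6),
        blue_pct=round(float(v[2]), 6),
        min_entropy=round(float(v[3]), 6),
        max_entropy=round(float(v[4]), 6),
        texture_coefficient=round(float(v[5]), 6),
        area=round(float(v[6]), 4),
        clusters=cluster_summaries,
        maturity=maturity.value,
        health=health.value,
        disease=disease.value,
        scores=scores,
    )


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> pd.DataFrame:
    labels = sorted(set(y_true) | set(y_pred))
    table = pd.DataFrame(0, index=labels, columns=labels)
    for t, p in zip(y_true, y_pred):
        table.loc[t, p] += 1
    return table


def evaluate(
    feature_table: pd.DataFrame, models: dict[str, TaskModel]
) -> dict[str, dict]:
    """Per-task accuracy and confusion matrices on a labelled feature table."""
    if feature_table.empty:
        raise DataError("cannot evaluate an empty feature table")
    X = _feature_matrix(feature_table)
    out: dict[str, dict] = {}
    for task, label_col in (
        ("maturity", "maturity_label"),
        ("health", "health_label"),
        ("disease", "disease_label"),
    ):
        if task not in models:
            continue
        if task == "disease":
            infected = (feature_table["health_label"] == HealthLabel.RISKY.value).to_numpy()
            if not infected.any():
                continue
            y_true = feature_table["disease_label"].to_numpy()[infected]
            y_pred = classify.predict_task(models[task], X[infected])
        else:
            y_true = feature_table[label_col].to_numpy()
            y_pred = classify.predict_task(models[task], X)
        out[task] = {
            "accuracy": float((y_true == y_pred).mean() * 100.0),
            "n": int(y_true.size),
            "confusion": _confusion(y_true, y_pred),
        }
    return out


def _stratified_split(
    labels: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def health_holdout_accuracy(
    seed: int,
    n_healthy: int = 62,
    n_infected: int = 38,
    train_frac: float = 0.7,
    config: PipelineConfig = PipelineConfig(),
) -> float:
    """Healthy-vs-risky holdout accuracy (%) of the end-to-end pipeline.

    Generates the dataset in memory, extracts features for every sample,
    trains the configured health classifier on a stratified ``train_frac``
    split, and scores the remainder. Deterministic in ``seed``.
    """
    specs = synthgen.plan_dataset(n_healthy, n_infected, seed=seed)
    rows = []
    labels = []
    for i, spec in enumerate(specs):
        background, sample, truth = synthgen.generate_sample(spec)
        fv, _, _ = extract_sample_features(
            background, sample, config, sample_id=f"sample_{i:04d}"
        )
        rows.append(fv.values)
        labels.append(truth.health_label.value)
    X = np.vstack(rows)
    y = np.array(labels)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = _stratified_split(y, train_frac, rng)
    model = classify.fit_task_model(
        X[train_idx], y[train_idx], task="health",
        classifier=config.classifier, knn_k=config.knn_k,
    )
    pred = classify.predict_task(model, X[test_idx])
    return float((pred == y[test_idx]).mean() * 100.0)
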