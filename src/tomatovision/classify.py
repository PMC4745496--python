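"""Statistical classifiers and the fruit-quality decision layer.

The four classifiers — PCA projection, linear and quadratic discriminant
analysis, and k-nearest-neighbors — are implemented directly from their
defining equations on top of numpy/scipy linear algebra:

* PCA: eigendecomposition of the mean-centered covariance C, components
  sorted by descending eigenvalue, projection Y = XV.
* LDA: directions maximizing the between-class to within-class scatter
  ratio (generalized eigenproblem Sb v = λ Sw v); classification by the
  linear discriminant scores D_i = b0 + Σ b_k x_k derived from class means,
  the pooled covariance and the class priors.
* QDA: per-class mean μ_k, covariance Σ_k = (1/n_k) Σ (x−μ_k)(x−μ_k)ᵀ and
  prior π_k; label = argmin_k (x−μ_k)ᵀ Σ_k⁻¹ (x−μ_k) − 2 log π_k + log|Σ_k|.
* KNN: majority vote among the k Euclidean-nearest training points; ties
  broken by the nearest single neighbor, then by the lowest class index.

The decision layer maps feature vectors to a maturity stage, a
healthy-vs-risky status, and (for risky fruit) a disease archetype.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import linalg

from .exceptions import DataError, ModelStateError, ParameterError, ShapeError
from .features import DISEASE_FEATURE_NAMES, ClusterSet

__all__ = [
    "FeatureVector",
    "FEATURE_NAMES",
    "MATURITY_FEATURE_INDICES",
    "HEALTH_FEATURE_INDICES",
    "DISEASE_FEATURE_INDICES",
    "MaturityLabel",
    "ExtendedStage",
    "HealthLabel",
    "DiseaseLabel",
    "PcaModel",
    "pca_fit",
    "pca_transform",
    "LdaModel",
    "lda_fit",
    "lda_predict",
    "QdaModel",
    "qda_fit",
    "qda_predict",
    "KnnModel",
    "knn_fit",
    "knn_predict",
    "TaskModel",
    "fit_task_model",
    "predict_task",
    "save_model",
    "load_model",
    "assess_maturity",
    "classify_health",
    "classify_disease",
]

# ---------------------------------------------------------------------------
# Labels

class MaturityLabel(str, Enum):
    UNRIPE = "u"
    MEDIUM = "m"
    RIPE = "r"


class ExtendedStage(str, Enum):
    """Optional four-stage ripeness scheme."""

    UNRIPE = "unripe"
    RIPEN = "ripen"
    FULLY_RIPEN = "fully_ripen"
    ROTTEN = "rotten"


class HealthLabel(str, Enum):
    HEALTHY = "healthy"
    RISKY = "risky"


class DiseaseLabel(str, Enum):
    EARLY_BLIGHT = "early_blight"
    LATE_BLIGHT = "late_blight"
    BACTERIAL_CANKER = "bacterial_canker"
    GRAY_MOLD = "gray_mold"
    BACTERIAL_SPECK = "bacterial_speck"
    NONE = "none"


#: Full surface-disease taxonomy. The first five entries are classified (the
#: synthetic generator renders their morphology); the rest are retained as
#: labels for database interoperability but are not rendered or predicted.
DISEASE_TAXONOMY: tuple[str, ...] = (
    "early_blight",
    "late_blight",
    "bacterial_canker",
    "gray_mold",
    "bacterial_speck",
    "anthracnose",
    "bacterial_spot",
    "tomato_spotted_wilt_virus",
    "blossom_end_rot",
    "fruit_cracking",
    "cat_faced_fruit",
    "sunscald",
    "blotchy_ripening",
    "target_spot",
    "cloudy_spot",
)


# ---------------------------------------------------------------------------
# Feature vector schema (k = 4 clusters)

_N_CLUSTERS = 4
_BASE_FEATURE_NAMES = (
    "red_pct",
    "green_pct",
    "blue_pct",
    "min_entropy",
    "max_entropy",
    "texture_coefficient",
    "area",
) + tuple(
    name
    for j in range(1, _N_CLUSTERS + 1)
    for name in (f"cluster{j}_contrast", f"cluster{j}_rel_area")
)
FEATURE_NAMES: tuple[str, ...] = _BASE_FEATURE_NAMES + DISEASE_FEATURE_NAMES

MATURITY_FEATURE_INDICES = tuple(range(6))  # R, G, B, entropy extrema, coefficient
HEALTH_FEATURE_INDICES = tuple(range(len(FEATURE_NAMES)))
DISEASE_FEATURE_INDICES = tuple(
    range(len(_BASE_FEATURE_NAMES), len(FEATURE_NAMES))
)


@dataclass(frozen=True)
class FeatureVector:
    """Fixed-order per-sample feature vector (see :data:`FEATURE_NAMES`)."""

    sample_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ShapeError(
                f"feature vector must have {len(FEATURE_NAMES)} entries, "
                f"got {self.values.shape}"
            )


# ---------------------------------------------------------------------------
# Helpers

def _as_matrix(data: np.ndarray) -> np.ndarray:
    X = np.asarray(data, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ShapeError(f"expected a 2-D data matrix, got shape {X.shape}")
    return X


def _check_dim(X: np.ndarray, p: int) -> None:
    if X.shape[1] != p:
        raise ShapeError(f"model expects {p} features, data has {X.shape[1]}")


def _regularize(cov: np.ndarray) -> np.ndarray:
    """Add eps*I (eps = 1e-6 trace/p) until the matrix is positive-definite."""
    p = cov.shape[0]
    eps = 1e-6 * max(np.trace(cov), 1e-12) / p
    out = cov.copy()
    for _ in range(40):
        try:
            linalg.cholesky(out, lower=True)
            return out
        except linalg.LinAlgError:
            out = out + eps * np.eye(p)
            eps *= 10.0
    raise DataError("covariance could not be regularized to positive-definite")


# ---------------------------------------------------------------------------
# PCA

@dataclass(frozen=True)
class PcaModel:
    mean: np.ndarray            # (p,)
    eigenvalues: np.ndarray     # (p,) descending, >= 0
    components: np.ndarray      # (p, n_components), orthonormal columns
    n_components: int


def pca_fit(data: np.ndarray, n_components: int | None = None) -> PcaModel:
    """Principal components of mean-centered data.

    The covariance (ddof=1) is eigendecomposed and components sorted by
    descending eigenvalue, so the eigenvalue sum equals the total variance of
    the centered data. Component signs are fixed (largest-magnitude loading
    positive) for determinism.
    """
    X = _as_matrix(data)
    n, p = X.shape
    if n < 2:
        raise DataError(f"PCA needs at least 2 samples, got {n}")
    if n_components is None:
        n_components = p
    if not 1 <= n_components <= p:
        raise ParameterError(f"n_components must be in [1, {p}], got {n_components}")
    mean = X.mean(axis=0)
    centered = X - mean
    cov = centered.T @ centered / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    flip = np.sign(eigvecs[np.abs(eigvecs).argmax(axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip
    return PcaModel(
        mean=mean,
        eigenvalues=eigvals,
        components=eigvecs[:, :n_components],
        n_components=n_components,
    )


def pca_transform(model: PcaModel, data: np.ndarray) -> np.ndarray:
    """Project data onto the retained components: Y = (X − mean) V."""
    X = _as_matrix(data)
    _check_dim(X, model.mean.shape[0])
    return (X - model.mean) @ model.components


# ---------------------------------------------------------------------------
# LDA

@dataclass(frozen=True)
class LdaModel:
    classes: np.ndarray         # (K,) sorted labels
    means: np.ndarray           # (K, p)
    coef: np.ndarray            # (K, p) discriminant weights b_k
    intercept: np.ndarray       # (K,)  discriminant intercepts b_0
    scalings: np.ndarray        # (p, K-1) scatter-ratio-maximizing directions
    priors: np.ndarray          # (K,)


def lda_fit(data: np.ndarray, labels: np.ndarray) -> LdaModel:
    """Fit multi-class linear discriminant analysis.

    Projection directions solve the generalized eigenproblem Sb v = λ Sw v
    (between- vs within-class scatter). Classification uses the linear
    scores D_i(x) = b0_i + b_iᵀ x with b_i = Σ_pooled⁻¹ μ_i and
    b0_i = −½ μ_iᵀ Σ_pooled⁻¹ μ_i + log π_i. The within-class scatter is
    regularized if singular.
    """
    X = _as_matrix(data)
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ShapeError("labels length must match data rows")
    classes = np.unique(y)
    if classes.size < 2:
        raise DataError("LDA needs at least 2 classes")
    n, p = X.shape
    means = np.empty((classes.size, p))
    priors = np.empty(classes.size)
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    grand = X.mean(axis=0)
    for i, c in enumerate(classes):
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise DataError(f"class {c!r} has fewer than 2 samples")
        means[i] = Xc.mean(axis=0)
        priors[i] = Xc.shape[0] / n
        dev = Xc - means[i]
        sw += dev.T @ dev
        dm = (means[i] - grand)[:, None]
        sb += Xc.shape[0] * (dm @ dm.T)
    sw_reg = _regularize(sw)
    eigvals, eigvecs = linalg.eigh(sb, sw_reg)
    order = np.argsort(eigvals)[::-1][: classes.size - 1]
    scalings = eigvecs[:, order]

    pooled = _regularize(sw_reg / (n - classes.size))
    pooled_inv = linalg.inv(pooled)
    coef = means @ pooled_inv
    intercept = -0.5 * np.einsum("ij,ij->i", coef, means) + np.log(priors)
    return LdaModel(
        classes=classes,
        means=means,
        coef=coef,
        intercept=intercept,
        scalings=scalings,
        priors=priors,
    )


def lda_predict(model: LdaModel, data: np.ndarray) -> np.ndarray:
    """Labels maximizing the linear discriminant score; ties break to the
    lowest class index."""
    X = _as_matrix(data)
    _check_dim(X, model.means.shape[1])
    scores = X @ model.coef.T + model.intercept
    return model.classes[scores.argmax(axis=1)]


# ---------------------------------------------------------------------------
# QDA

@dataclass(frozen=True)
class QdaModel:
    classes: np.ndarray
    means: np.ndarray           # (K, p)
    covariances: np.ndarray     # (K, p, p), regularized positive-definite
    priors: np.ndarray          # (K,), sums to 1
    _precisions: np.ndarray = field(repr=False, default=None)
    _logdets: np.ndarray = field(repr=False, default=None)


def qda_fit(data: np.ndarray, labels: np.ndarray) -> QdaModel:
    """Per-class Gaussian fit: mean, covariance Σ_k = (1/n_k) Σ devᵀdev,
    and prior π_k = n_k / n; covariances regularized to positive-definite."""
    X = _as_matrix(data)
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ShapeError("labels length must match data rows")
    classes = np.unique(y)
    if classes.size < 1:
        raise DataError("QDA needs at least 1 class")
    n, p = X.shape
    means = np.empty((classes.size, p))
    covs = np.empty((classes.size, p, p))
    priors = np.empty(classes.size)
    for i, c in enumerate(classes):
        Xc = X[y == c]
        if Xc.shape[0] == 0:
            raise DataError(f"class {c!r} is empty")
        means[i] = Xc.mean(axis=0)
        dev = Xc - means[i]
        covs[i] = _regularize(dev.T @ dev / Xc.shape[0])
        priors[i] = Xc.shape[0] / n
    precisions = np.stack([linalg.inv(covs[i]) for i in range(classes.size)])
    logdets = np.array(
        [float(np.linalg.slogdet(covs[i])[1]) for i in range(classes.size)]
    )
    return QdaModel(
        classes=classes,
        means=means,
        covariances=covs,
        priors=priors,
        _precisions=precisions,
        _logdets=logdets,
    )


def qda_discriminants(model: QdaModel, data: np.ndarray) -> np.ndarray:
    """The quadratic discriminant (x−μ_k)ᵀΣ_k⁻¹(x−μ_k) − 2 log π_k + log|Σ_k|
    for every sample and class; lower is better."""
    X = _as_matrix(data)
    _check_dim(X, model.means.shape[1])
    K = model.classes.size
    out = np.empty((X.shape[0], K))
    for i in range(K):
        dev = X - model.means[i]
        maha = np.einsum("nj,jk,nk->n", dev, model._precisions[i], dev)
        out[:, i] = maha - 2.0 * np.log(model.priors[i]) + model._logdets[i]
    return out


def qda_predict(model: QdaModel, data: np.ndarray) -> np.ndarray:
    """Labels minimizing the quadratic discriminant; ties break to the lowest
    class index."""
    return model.classes[qda_discriminants(model, data).argmin(axis=1)]


# ---------------------------------------------------------------------------
# KNN

@dataclass(frozen=True)
class KnnModel:
    train_data: np.ndarray
    train_labels: np.ndarray
    k: int


def knn_fit(data: np.ndarray, labels: np.ndarray, k: int = 5) -> KnnModel:
    X = _as_matrix(data)
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ShapeError("labels length must match data rows")
    if not 1 <= k <= X.shape[0]:
        raise ParameterError(f"k must be in [1, {X.shape[0]}], got {k}")
    return KnnModel(train_data=X, train_labels=y, k=k)


def knn_neighbors(model: KnnModel, data: np.ndarray) -> np.ndarray:
    """Indices of the k nearest training points per query, nearest first;
    exact distance ties resolve to the lower training index (stable sort)."""
    X = _as_matrix(data)
    _check_dim(X, model.train_data.shape[1])
    d2 = (
        (X ** 2).sum(axis=1)[:, None]
        - 2.0 * X @ model.train_data.T
        + (model.train_data ** 2).sum(axis=1)[None, :]
    )
    return np.argsort(d2, axis=1, kind="stable")[:, : model.k]


def knn_predict(model: KnnModel, data: np.ndarray) -> np.ndarray:
    """Majority label among the k Euclidean-nearest training points.

    Vote ties break to the class of the nearest neighbor among the tied
    classes, then to the lowest class index.
    """
    neighbors = knn_neighbors(model, data)
    classes = np.unique(model.train_labels)
    class_index = {c: i for i, c in enumerate(classes)}
    out = np.empty(neighbors.shape[0], dtype=model.train_labels.dtype)
    for q in range(neighbors.shape[0]):
        labs = model.train_labels[neighbors[q]]
        counts = np.zeros(classes.size, dtype=int)
        for lab in labs:
            counts[class_index[lab]] += 1
        best = counts.max()
        tied = {classes[i] for i in np.flatnonzero(counts == best)}
        if len(tied) == 1:
            out[q] = next(iter(tied))
        else:
            # nearest neighbor whose class is tied wins (neighbors are
            # distance-ordered, equal distances resolve to lower index,
            # which also realizes the lowest-class-index fallback)
            out[q] = next(lab for lab in labs if lab in tied)
    return out


# ---------------------------------------------------------------------------
# Decision layer

_CLASSIFIER_CHOICES = ("knn", "lda", "qda", "pca+knn")


@dataclass(frozen=True)
class TaskModel:
    """A trained decision-layer model for one task.

    Bundles the feature sub-vector selection, a z-score standardization
    learned from the training set, an optional PCA reduction, and one of the
    four classifiers.
    """

    task: str                       # "maturity" | "health" | "disease"
    classifier: str                 # one of _CLASSIFIER_CHOICES
    feature_indices: tuple[int, ...]
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    pca: PcaModel | None
    inner: LdaModel | QdaModel | KnnModel


_TASK_INDICES = {
    "maturity": MATURITY_FEATURE_INDICES,
    "health": HEALTH_FEATURE_INDICES,
    "disease": DISEASE_FEATURE_INDICES,
}


def fit_task_model(
    data: np.ndarray,
    labels: np.ndarray,
    task: str,
    classifier: str = "knn",
    knn_k: int = 5,
    n_components: int | None = None,
) -> TaskModel:
    """Train a decision-layer model on full feature vectors.

    ``data`` holds one full-length feature vector per row; the task's
    sub-vector is selected, standardized, optionally PCA-reduced
    (``classifier='pca+knn'``), and the chosen classifier is fitted.
    """
    if task not in _TASK_INDICES:
        raise ParameterError(f"unknown task {task!r}")
    if classifier not in _CLASSIFIER_CHOICES:
        raise ParameterError(f"classifier must be one of {_CLASSIFIER_CHOICES}")
    X = _as_matrix(data)[:, _TASK_INDICES[task]]
    y = np.asarray(labels)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Z = (X - mean) / std
    pca = None
    if classifier == "pca+knn":
        n_comp = n_components or min(Z.shape[1], max(2, Z.shape[1] // 2))
        pca = pca_fit(Z, n_components=n_comp)
        Z = pca_transform(pca, Z)
    if classifier in ("knn", "pca+knn"):
        inner = knn_fit(Z, y, k=min(knn_k, Z.shape[0]))
    elif classifier == "lda":
        inner = lda_fit(Z, y)
    else:
        inner = qda_fit(Z, y)
    return TaskModel(
        task=task,
        classifier=classifier,
        feature_indices=tuple(_TASK_INDICES[task]),
        scaler_mean=mean,
        scaler_std=std,
        pca=pca,
        inner=inner,
    )


def predict_task(model: TaskModel, data: np.ndarray) -> np.ndarray:
    """Predicted labels for rows of full-length feature vectors."""
    if not isinstance(model, TaskModel):
        raise ModelStateError("expected a trained TaskModel")
    X = _as_matrix(data)
    if X.shape[1] == len(FEATURE_NAMES):
        X = X[:, list(model.feature_indices)]
    elif X.shape[1] != len(model.feature_indices):
        raise ShapeError(
            f"expected {len(FEATURE_NAMES)} or {len(model.feature_indices)} "
            f"features, got {X.shape[1]}"
        )
    Z = (X - model.scaler_mean) / model.scaler_std
    if model.pca is not None:
        Z = pca_transform(model.pca, Z)
    if isinstance(model.inner, KnnModel):
        return knn_predict(model.inner, Z)
    if isinstance(model.inner, LdaModel):
        return lda_predict(model.inner, Z)
    return qda_predict(model.inner, Z)


def task_scores(model: TaskModel, data: np.ndarray) -> list[dict[str, float]]:
    """Per-class scores for each row: neighbor vote shares for KNN (higher is
    better), linear discriminant scores for LDA, negated quadratic
    discriminants for QDA (so higher is better everywhere)."""
    X = _as_matrix(data)
    if X.shape[1] == len(FEATURE_NAMES):
        X = X[:, list(model.feature_indices)]
    Z = (X - model.scaler_mean) / model.scaler_std
    if model.pca is not None:
        Z = pca_transform(model.pca, Z)
    if isinstance(model.inner, KnnModel):
        classes = np.unique(model.inner.train_labels)
        neighbors = knn_neighbors(model.inner, Z)
        out = []
        for row in neighbors:
            labs = model.inner.train_labels[row]
            out.append(
                {str(c): float((labs == c).mean()) for c in classes}
            )
        return out
    if isinstance(model.inner, LdaModel):
        scores = Z @ model.inner.coef.T + model.inner.intercept
        return [
            {str(c): float(s) for c, s in zip(model.inner.classes, row)}
            for row in scores
        ]
    scores = -qda_discriminants(model.inner, Z)
    return [
        {str(c): float(s) for c, s in zip(model.inner.classes, row)}
        for row in scores
    ]


def assess_maturity(features: FeatureVector, model: TaskModel) -> MaturityLabel:
    """Ripeness stage from the color/entropy sub-vector."""
    if model.task != "maturity":
        raise ModelStateError(f"model was trained for task {model.task!r}")
    return MaturityLabel(predict_task(model, features.values[None, :])[0])


def classify_health(features: FeatureVector, model: TaskModel) -> HealthLabel:
    """Healthy-vs-risky status from the full feature vector."""
    if model.task != "health":
        raise ModelStateError(f"model was trained for task {model.task!r}")
    return HealthLabel(predict_task(model, features.values[None, :])[0])


def classify_disease(
    clusters: ClusterSet,
    features: FeatureVector,
    model: TaskModel,
    health: HealthLabel = HealthLabel.RISKY,
) -> DiseaseLabel:
    """Disease archetype from the lesion descriptors of a risky sample.

    Calling this on a healthy sample returns :attr:`DiseaseLabel.NONE` with
    a warning rather than inventing a disease.
    """
    if model.task != "disease":
        raise ModelStateError(f"model was trained for task {model.task!r}")
    if health == HealthLabel.HEALTHY:
        warnings.warn("classify_disease called on a healthy sample", stacklevel=2)
        return DiseaseLabel.NONE
    return DiseaseLabel(predict_task(model, features.values[None, :])[0])


# ---------------------------------------------------------------------------
# Serialization (versioned JSON: portable, endianness-safe)

_MODEL_FORMAT = "tomatovision.model/1"


def _arr(a: np.ndarray) -> list:
    return np.asarray(a).tolist()


def _inner_to_json(inner) -> dict:
    if isinstance(inner, KnnModel):
        return {
            "kind": "knn",
            "train_data": _arr(inner.train_data),
            "train_labels": [str(v) for v in inner.train_labels],
            "k": inner.k,
        }
    if isinstance(inner, LdaModel):
        return {
            "kind": "lda",
            "classes": [str(v) for v in inner.classes],
            "means": _arr(inner.means),
            "coef": _arr(inner.coef),
            "intercept": _arr(inner.intercept),
            "scalings": _arr(inner.scalings),
            "priors": _arr(inner.priors),
        }
    if isinstance(inner, QdaModel):
        return {
            "kind": "qda",
            "classes": [str(v) for v in inner.classes],
            "means": _arr(inner.means),
            "covariances": _arr(inner.covariances),
            "priors": _arr(inner.priors),
        }
    raise ModelStateError(f"unserializable inner model {type(inner)!r}")


def _inner_from_json(d: dict):
    kind = d["kind"]
    if kind == "knn":
        return KnnModel(
            train_data=np.asarray(d["train_data"], dtype=np.float64),
            train_labels=np.asarray(d["train_labels"]),
            k=int(d["k"]),
        )
    if kind == "lda":
        return LdaModel(
            classes=np.asarray(d["classes"]),
            means=np.asarray(d["means"], dtype=np.float64),
            coef=np.asarray(d["coef"], dtype=np.float64),
            intercept=np.asarray(d["intercept"], dtype=np.float64),
            scalings=np.asarray(d["scalings"], dtype=np.float64),
            priors=np.asarray(d["priors"], dtype=np.float64),
        )
    if kind == "qda":
        covs = np.asarray(d["covariances"], dtype=np.float64)
        precisions = np.stack([linalg.inv(c) for c in covs])
        logdets = np.array([float(np.linalg.slogdet(c)[1]) for c in covs])
        return QdaModel(
            classes=np.asarray(d["classes"]),
            means=np.asarray(d["means"], dtype=np.float64),
            covariances=covs,
            priors=np.asarray(d["priors"], dtype=np.float64),
            _precisions=precisions,
            _logdets=logdets,
        )
    raise ModelStateError(f"unknown model kind {kind!r}")


def save_model(model: TaskModel, path: str | Path) -> None:
    """Serialize a TaskModel to versioned JSON (deterministic byte layout)."""
    payload = {
        "format": _MODEL_FORMAT,
        "task": model.task,
        "classifier": model.classifier,
        "feature_indices": list(model.feature_indices),
        "scaler_mean": _arr(model.scaler_mean),
        "scaler_std": _arr(model.scaler_std),
        "pca": None
        if model.pca is None
        else {
            "mean": _arr(model.pca.mean),
            "eigenvalues": _arr(model.pca.eigenvalues),
            "components": _arr(model.pca.components),
            "n_components": model.pca.n_components,
        },
        "inner": _inner_to_json(model.inner),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def load_model(path: str | Path) -> TaskModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != _MODEL_FORMAT:
        raise ModelStateError(
            f"unrecognized model format {payload.get('format')!r} in {path}"
        )
    pca = None
    if payload["pca"] is not None:
        d = payload["pca"]
        pca = PcaModel(
            mean=np.asarray(d["mean"], dtype=np.float64),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=np.float64),
            components=np.asarray(d["components"], dtype=np.float64),
            n_components=int(d["n_components"]),
        )
    return TaskModel(
        task=payload["task"],
        classifier=payload["classifier"],
        feature_indices=tuple(payload["feature_indices"]),
        scaler_mean=np.asarray(payload["scaler_mean"], dtype=np.float64),
        scaler_std=np.asarray(payload["scaler_std"], dtype=np.float64),
        pca=pca,
        inner=_inner_from_json(payload["inner"]),
    )
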