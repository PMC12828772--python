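"""Linear discriminant analysis on cell-type compositions.

The subtype classifier is plain LDA: class-conditional Gaussians with a
pooled covariance. Because the 8 composition features sum to one, the
pooled covariance is singular; a small recorded ridge restores positive
definiteness. Models serialize to versioned JSON so a classifier trained on
one cohort can label another.

Features are raw proportions (not z-scores): cross-cohort prediction with
per-cohort standardization would be ill-defined, since each cohort would be
scaled by its own statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import COMPONENTS, CompositionMatrix, SubtypeLabeling

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


class ModelError(ValueError):
    """Raised for invalid training data or corrupted model files."""


def _as_frame(comp: CompositionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Accept the pipeline's CompositionMatrix or any plain feature frame."""
    return comp.proportions if isinstance(comp, CompositionMatrix) else comp


@dataclass
class LdaModel:
    """Serializable LDA state: class means, pooled covariance, priors."""

    class_names: list[str]
    class_means: np.ndarray  # n_classes x n_features
    pooled_covariance: np.ndarray  # n_features x n_features
    priors: np.ndarray  # n_classes
    feature_names: list[str]
    n_per_class: dict[str, int]
    regularization: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(self.priors > 0) or abs(self.priors.sum() - 1) > 1e-9:
            raise ModelError("priors must be positive and sum to 1")
        eigvals = np.linalg.eigvalsh(self.pooled_covariance)
        if eigvals.min() <= 0:
            raise ModelError("pooled covariance must be positive definite (after regularization)")


def train_lda(
    comp: CompositionMatrix,
    labels: SubtypeLabeling,
    priors: dict[str, float] | None = None,
) -> LdaModel:
    """Fit LDA from labeled compositions.

    Class means are per-class feature averages; the pooled covariance is the
    within-class scatter divided by N - n_classes. If it is singular (the
    simplex features are linearly dependent, so it always is on raw
    compositions), a ridge of ``1e-8 * trace / n_features`` is added and
    recorded on the model. Priors default to empirical class frequencies.
    """
    X = _as_frame(comp)
    y = (labels.labels if isinstance(labels, SubtypeLabeling) else labels).reindex(X.index)
    if y.isna().any():
        missing = X.index[y.isna()].tolist()
        raise ModelError(f"samples without labels: {missing[:5]}")
    class_names = sorted(y.unique())
    counts = y.value_counts()
    too_small = [c for c in class_names if counts[c] < 2]
    if too_small:
        raise ModelError(f"classes with < 2 samples: {too_small}")
    if len(class_names) < 2:
        raise ModelError("need at least 2 classes")

    n, p = X.shape
    means = np.vstack([X[y == c].mean(axis=0).to_numpy() for c in class_names])
    scatter = np.zeros((p, p))
    for i, c in enumerate(class_names):
        D = X[y == c].to_numpy() - means[i]
        scatter += D.T @ D
    cov = scatter / (n - len(class_names))

    reg = 0.0
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < 1e-12 * max(eigvals.max(), 1.0):
        reg = 1e-8 * np.trace(cov) / p
        cov = cov + reg * np.eye(p)
        logger.info("singular pooled covariance; ridge %.3e added", reg)

    if priors is None:
        prior_vec = np.array([counts[c] / n for c in class_names])
    else:
        prior_vec = np.array([priors[c] for c in class_names], dtype=float)
        prior_vec = prior_vec / prior_vec.sum()

    return LdaModel(
        class_names=list(class_names),
        class_means=means,
        pooled_covariance=cov,
        priors=prior_vec,
        feature_names=list(X.columns),
        n_per_class={c: int(counts[c]) for c in class_names},
        regularization=reg,
    )


def predict_lda(
    model: LdaModel, comp: CompositionMatrix
) -> tuple[SubtypeLabeling, pd.DataFrame]:
    """Predict subtype labels and posterior probabilities for new samples.

    The discriminant is the standard linear score
    ``delta_c(x) = x' S^-1 mu_c - mu_c' S^-1 mu_c / 2 + log pi_c``;
    the label is its argmax and posteriors are its softmax (exact for the
    shared-covariance Gaussian model). Exact ties go to the first class in
    ``class_names`` order with a logged note.
    """
    frame = _as_frame(comp)
    missing = [f for f in model.feature_names if f not in frame.columns]
    if missing:
        raise ModelError(f"composition lacks model features: {missing}")
    X = frame[model.feature_names].to_numpy()
    Sinv_mu = np.linalg.solve(model.pooled_covariance, model.class_means.T)  # p x k
    const = -0.5 * np.einsum("ij,ji->i", model.class_means, Sinv_mu) + np.log(model.priors)
    delta = X @ Sinv_mu + const  # n x k

    best = delta.argmax(axis=1)
    sorted_delta = np.sort(delta, axis=1)
    ties = np.isclose(sorted_delta[:, -1], sorted_delta[:, -2], rtol=0, atol=1e-12)
    if ties.any():
        logger.info("%d sample(s) on a decision boundary; tie broken by class order", ties.sum())

    shifted = delta - delta.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)

    labels = pd.Series([model.class_names[i] for i in best], index=frame.index, name="subtype")
    posteriors = pd.DataFrame(post, index=frame.index, columns=model.class_names)
    return SubtypeLabeling(labels), posteriors


def save_model(model: LdaModel, path: str | Path) -> None:
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "class_names": model.class_names,
        "class_means": model.class_means.tolist(),
        "pooled_covariance": model.pooled_covariance.tolist(),
        "priors": model.priors.tolist(),
        "feature_names": model.feature_names,
        "n_per_class": model.n_per_class,
        "regularization": model.regularization,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> LdaModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"cannot parse model file {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelError(f"unsupported model format version {version!r}")
    return LdaModel(
        class_names=payload["class_names"],
        class_means=np.array(payload["class_means"]),
        pooled_covariance=np.array(payload["pooled_covariance"]),
        priors=np.array(payload["priors"]),
        feature_names=payload["feature_names"],
        n_per_class={k: int(v) for k, v in payload["n_per_class"].items()},
        regularization=payload["regularization"],
    )
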