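"""PCA-LDA: principal component reduction followed by Fisher discriminants.

The comparison classifier for the spectral cohorts: PCA compresses the
~600-variable spectra into a handful of orthogonal score directions, and
Fisher linear discriminant analysis then separates the classes in that
reduced space.  LDA is always fitted on PCA scores, never on the raw
spectra, so the pooled within-class scatter stays well conditioned.

Classification assigns a sample to the nearest class mean in the
discriminant space (Mahalanobis metric via the generalized eigenproblem
``S_b v = lambda S_w v``), with equal class priors by default — the
diagnostic convention, so prevalence in the training cohort does not
bias the call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA


@dataclass
class PCAModel:
    mean: np.ndarray
    components: np.ndarray  # (p, k), orthonormal columns
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # training scores, (n, k)

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean.size:
            raise ValueError(
                f"X has {X.shape[1]} variables, PCA was fitted on {self.mean.size}"
            )
        return (X - self.mean) @ self.components


@dataclass
class LDAModel:
    class_labels: list[str]
    directions: np.ndarray  # (k, n_classes - 1), S_w-orthonormal
    class_means: np.ndarray  # projected class means, (n_classes, n_classes - 1)
    priors: np.ndarray

    def discriminant_scores(self, scores: np.ndarray) -> np.ndarray:
        """Per-class score: -(1/2) squared Mahalanobis distance + log prior."""
        z = np.atleast_2d(scores) @ self.directions
        d2 = ((z[:, None, :] - self.class_means[None, :, :]) ** 2).sum(axis=2)
        return -0.5 * d2 + np.log(self.priors)[None, :]


@dataclass
class PCALDAModel:
    """Composite model; serializable to JSON like the OPLS container."""

    pca: PCAModel
    lda: LDAModel
    labels: np.ndarray = field(default=None, repr=False)

    @property
    def class_labels(self) -> list[str]:
        return self.lda.class_labels

    def to_json(self, path: str | Path) -> None:
        payload = {
            "class_labels": self.lda.class_labels,
            "pca_mean": self.pca.mean.tolist(),
            "pca_components": self.pca.components.tolist(),
            "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
            "lda_directions": self.lda.directions.tolist(),
            "lda_class_means": self.lda.class_means.tolist(),
            "priors": self.lda.priors.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Centered-SVD PCA retaining ``n_components`` directions."""
    X = np.asarray(X, dtype=float)
    limit = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= limit:
        raise ValueError(
            f"n_components must be in [1, {limit}] for {X.shape[0]} samples x "
            f"{X.shape[1]} variables"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAModel(
        mean=pca.mean_,
        components=pca.components_.T,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
    )


def select_n_components(
    X: np.ndarray, variance_target: float = 0.95, cap_fraction: float = 1 / 3
) -> int:
    """Smallest PC count explaining >= ``variance_target`` of the variance,
    capped at ``cap_fraction`` of the sample count (and at least 2)."""
    X = np.asarray(X, dtype=float)
    full = fit_pca(X, min(X.shape[0] - 1, X.shape[1]))
    cum = np.cumsum(full.explained_variance_ratio)
    k = int(np.searchsorted(cum, variance_target) + 1)
    cap = max(2, int(X.shape[0] * cap_fraction))
    return max(2, min(k, cap))


def fit_lda(
    scores: np.ndarray,
    labels: Sequence,
    class_order: Sequence[str] | None = None,
    priors: Sequence[float] | None = None,
) -> LDAModel:
    """Fisher LDA on (PCA) scores from the pooled within-class scatter.

    Solves ``S_b v = lambda S_w v``; the retained eigenvectors are
    S_w-orthonormal, so Euclidean distance in the projected space is the
    pooled-covariance Mahalanobis distance restricted to the discriminant
    subspace.  Priors default to equal.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object).astype(str)
    order = [str(c) for c in class_order] if class_order is not None else sorted(set(labels))
    if len(order) < 2:
        raise ValueError("need at least 2 classes")
    n, k = scores.shape
    grand = scores.mean(axis=0)
    s_w = np.zeros((k, k))
    s_b = np.zeros((k, k))
    means = []
    for c in order:
        block = scores[labels == c]
        if block.shape[0] == 0:
            raise ValueError(f"class {c!r} has no samples")
        mu = block.mean(axis=0)
        means.append(mu)
        centered = block - mu
        s_w += centered.T @ centered
        s_b += block.shape[0] * np.outer(mu - grand, mu - grand)
    s_w /= n - len(order)
    try:
        evals, evecs = linalg.eigh(s_b, s_w)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-class scatter; retain fewer PCA components"
        ) from exc
    order_idx = np.argsort(evals)[::-1][: len(order) - 1]
    directions = evecs[:, order_idx]
    if priors is None:
        pri = np.full(len(order), 1.0 / len(order))
    else:
        pri = np.asarray(priors, dtype=float)
        pri = pri / pri.sum()
    return LDAModel(
        class_labels=order,
        directions=directions,
        class_means=np.vstack(means) @ directions,
        priors=pri,
    )


def fit_pcalda(
    X: np.ndarray,
    labels: Sequence,
    n_components: int | None = None,
    class_order: Sequence[str] | None = None,
    priors: Sequence[float] | None = None,
) -> PCALDAModel:
    """Two-stage fit: PCA (95%-variance rule by default) then Fisher LDA."""
    X = np.asarray(X, dtype=float)
    if n_components is None:
        n_components = select_n_components(X)
    pca = fit_pca(X, n_components)
    lda = fit_lda(pca.scores, labels, class_order=class_order, priors=priors)
    return PCALDAModel(
        pca=pca, lda=lda, labels=np.asarray(labels, dtype=object).astype(str)
    )


def predict_pcalda(model: PCALDAModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project new spectra and classify; returns (class scores, labels)."""
    z = model.pca.transform(X_new)
    scores = model.lda.discriminant_scores(z)
    labels = np.array(
        [model.class_labels[i] for i in np.argmax(scores, axis=1)], dtype=object
    )
    return scores, labels
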