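"""Comparison classifiers/projections: Fisher LDA and principal components.

LDA is the single-component, shared-covariance special case of the mixture
discriminant model; PCA is the label-blind variance-maximizing projection used
to contrast GSI on principal components with GSI on raw feature subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gmda import _ensure_spd, _mvn_logpdf
from .io import FeatureMatrix, LabelMap, align

__all__ = ["LdaModel", "PcaProjection", "fit_lda", "pca_project"]


@dataclass
class LdaModel:
    """Gaussian classifier with class-specific means and one pooled covariance."""

    class_labels: tuple[str, str]
    class_means: np.ndarray  # (2, d)
    pooled_covariance: np.ndarray  # (d, d), ML (1/n) estimate
    class_priors: np.ndarray  # (2,)

    def log_joint(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        with np.errstate(divide="ignore"):
            lp = np.log(self.class_priors)
        return np.column_stack(
            [lp[j] + _mvn_logpdf(X, self.class_means[j], self.pooled_covariance) for j in range(2)]
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        lj = self.log_joint(X)
        lj = np.where(np.isneginf(lj), -1e300, lj)
        e = np.exp(lj - lj.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict_index(self, X: np.ndarray) -> np.ndarray:
        post = self.predict_proba(X)
        return (post[:, 1] > post[:, 0]).astype(int)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array(self.class_labels, dtype=object)[self.predict_index(X)]


def fit_lda(data: FeatureMatrix, labels: LabelMap) -> LdaModel:
    """Fit Fisher LDA: sample class means, pooled within-class ML covariance."""
    data, labels = align(data, labels)
    labels.require_two_classes()
    y = labels.y(data.gene_ids)
    d = data.n_features
    Xs = [data.values[y == j] for j in range(2)]
    for lab, X in zip(labels.classes, Xs):
        if X.shape[0] < d + 1:
            raise ValueError(f"class {lab!r} has {X.shape[0]} points; need at least d+1 = {d + 1}")
    means = np.stack([X.mean(axis=0) for X in Xs])
    n = sum(X.shape[0] for X in Xs)
    pooled = sum((X - m).T @ (X - m) for X, m in zip(Xs, means)) / n
    scale = float(np.trace(pooled) / d) or 1.0
    pooled = _ensure_spd(pooled, scale)
    priors = np.array([X.shape[0] / n for X in Xs])
    return LdaModel(tuple(labels.classes), means, pooled, priors)


@dataclass
class PcaProjection:
    """Orthonormal loadings of the first m principal components.

    Computed from the centered (not rescaled) data: all features share the
    log2-fold-change scale.  Loadings are sign-fixed so the largest-magnitude
    element of each column is positive.
    """

    loadings: np.ndarray  # (d, m)
    center: np.ndarray  # (d,)
    variance_explained: np.ndarray  # (m,) fractions of total variance

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.center) @ self.loadings


def pca_project(data: FeatureMatrix, m: int) -> tuple[PcaProjection, FeatureMatrix]:
    """Project onto the first m PCs; returns the projection and the score matrix."""
    X = data.values
    n, d = X.shape
    if not 1 <= m <= d:
        raise ValueError(f"m must be in [1, {d}], got {m}")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(n, d) * np.finfo(float).eps)) if s.size else 0
    if m > rank:
        raise ValueError(f"m={m} exceeds the data rank {rank}")
    eigvals = s**2 / n
    loadings = Vt[:m].T.copy()
    # sign convention: largest-|.| element of each loading positive
    for j in range(m):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    var_explained = eigvals[:m] / eigvals.sum()
    scores = Xc @ loadings
    score_fm = FeatureMatrix(
        list(data.gene_ids), [f"PC{j + 1}" for j in range(m)], scores
    )
    return PcaProjection(loadings, center, var_explained), score_fm
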