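"""Scatterplots with fitted-component covariance ellipses.

Reproduces the projection views the ranking is meant to surface: class-colored
points, one ellipse per fitted mixture component (Mahalanobis contour at a
chi-square probability level), a dashed square at +/- 1 log2 unit (the 2-fold
change boundary), and labeled outlier genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.stats import chi2, gaussian_kde

from .gmda import GmdaModel
from .io import FeatureMatrix, LabelMap, align

__all__ = [
    "EllipseOutline",
    "ellipse_outline",
    "scatterplot",
    "scatterplot_matrix",
    "suggest_outliers",
]

_CLASS_COLORS = ("#1f77b4", "#d62728")


@dataclass
class EllipseOutline:
    """Closed polyline tracing a Mahalanobis contour of a 2-D Gaussian."""

    center: np.ndarray
    polyline: np.ndarray  # (n_points + 1, 2), first point repeated at the end
    level: float


def ellipse_outline(
    mean: np.ndarray, covariance: np.ndarray, level: float = 0.95, n_points: int = 200
) -> EllipseOutline:
    """Contour {x : (x-mu)' Sigma^-1 (x-mu) = chi2_2.ppf(level)} as a polyline."""
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(covariance, dtype=float)
    if mean.shape != (2,) or cov.shape != (2, 2):
        raise ValueError("ellipse_outline is 2-D only")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    eigvals, eigvecs = np.linalg.eigh(0.5 * (cov + cov.T))
    if np.any(eigvals <= 0):
        raise ValueError("covariance must be positive-definite")
    r = np.sqrt(chi2.ppf(level, df=2))
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    pts = mean + (circle * np.sqrt(eigvals) * r) @ eigvecs.T
    closed = np.vstack([pts, pts[:1]])
    return EllipseOutline(mean.copy(), closed, level)


def suggest_outliers(
    fm: FeatureMatrix, labels: LabelMap, model: GmdaModel, quantile: float = 0.05
) -> list[str]:
    """Genes whose own-class mixture density falls in the lowest ``quantile``.

    A plotting convenience for choosing which points to label; callers
    remain free to pass any gene list to :func:`scatterplot` instead.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    fm, labels = align(fm, labels)
    y = labels.y(fm.gene_ids)
    dens = np.empty(fm.n_genes)
    for j in range(2):
        mask = y == j
        if mask.any():
            dens[mask] = model.class_mixtures[j].logpdf(fm.values[mask])
    cut = np.quantile(dens, quantile)
    return [g for g, d in zip(fm.gene_ids, dens) if d <= cut]


def _draw_panel(ax, X, y, feature_x, feature_y, classes, model, pair_idx, ellipse_level):
    for j, lab in enumerate(classes):
        pts = X[y == j]
        ax.scatter(pts[:, 0], pts[:, 1], s=12, alpha=0.75, color=_CLASS_COLORS[j], label=lab)
    if model is not None:
        for j in range(2):
            for comp in model.class_mixtures[j].components:
                mu = comp.mean[list(pair_idx)]
                cov = comp.covariance[np.ix_(pair_idx, pair_idx)]
                out = ellipse_outline(mu, cov, level=ellipse_level)
                ax.plot(out.polyline[:, 0], out.polyline[:, 1],
                        color=_CLASS_COLORS[j], lw=1.4)
    sq = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1], [-1, -1]], dtype=float)
    ax.plot(sq[:, 0], sq[:, 1], ls="--", color="gray", lw=1.0)
    ax.set_xlabel(feature_x)
    ax.set_ylabel(feature_y)


def scatterplot(
    fm: FeatureMatrix,
    labels: LabelMap,
    model: GmdaModel | None = None,
    outliers: Sequence[str] = (),
    out: str | Path | None = None,
    ellipse_level: float = 0.95,
    ax=None,
):
    """Two-feature scatterplot with component ellipses and the +/-1 log2 square.

    ``outliers`` are gene ids to highlight and label by name.  Writes PNG/SVG
    when ``out`` is given; returns the matplotlib Axes.
    """
    if fm.n_features != 2:
        raise ValueError(
            f"scatterplot needs exactly 2 features (got {fm.n_features}); "
            "use scatterplot_matrix for 3 or 4"
        )
    fm, labels = align(fm, labels)
    labels.require_two_classes()
    y = labels.y(fm.gene_ids)
    own_fig = ax is None
    if own_fig:
        fig, ax = plt.subplots(figsize=(6, 6))
    _draw_panel(ax, fm.values, y, fm.feature_ids[0], fm.feature_ids[1],
                labels.classes, model, (0, 1), ellipse_level)
    for g in outliers:
        if g in fm.gene_ids:
            xy = fm.row(g)
            ax.scatter(*xy, s=40, facecolors="none", edgecolors="black", zorder=3)
            ax.annotate(g, xy, textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.legend(frameon=False)
    if out is not None and own_fig:
        fig.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


def scatterplot_matrix(
    fm: FeatureMatrix,
    labels: LabelMap,
    model: GmdaModel | None = None,
    out: str | Path | None = None,
    ellipse_level: float = 0.95,
):
    """M x M pairwise-panel grid (M in {3, 4}); diagonal shows class densities."""
    M = fm.n_features
    if M not in (3, 4):
        raise ValueError(f"scatterplot_matrix needs 3 or 4 features, got {M}")
    fm, labels = align(fm, labels)
    labels.require_two_classes()
    y = labels.y(fm.gene_ids)
    fig, axes = plt.subplots(M, M, figsize=(3 * M, 3 * M))
    for a in range(M):
        for b in range(M):
            ax = axes[a, b]
            if a == b:
                xs = np.linspace(fm.values[:, a].min() - 1, fm.values[:, a].max() + 1, 200)
                for j, lab in enumerate(labels.classes):
                    v = fm.values[y == j, a]
                    if len(v) > 1 and np.std(v) > 0:
                        ax.plot(xs, gaussian_kde(v)(xs), color=_CLASS_COLORS[j], label=lab)
                ax.set_xlabel(fm.feature_ids[a])
                if a == 0:
                    ax.legend(frameon=False, fontsize=8)
            else:
                _draw_panel(
                    ax, fm.values[:, [b, a]], y, fm.feature_ids[b], fm.feature_ids[a],
                    labels.classes, model, (b, a), ellipse_level,
                )
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
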