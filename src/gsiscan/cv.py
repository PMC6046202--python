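"""Stratified repeated cross-validation and the group separation index.

The separation between two gene classes on a feature subset is quantified as

    GSI = 1 - e_rcv,

where ``e_rcv`` is the repeated stratified K-fold cross-validated
misclassification error rate (MER) of the mixture discriminant classifier.
MER estimates the total probability of misclassification (TPM)

    TPM = p1 * P(2|1) + p2 * P(1|2)

with priors taken as the observed class proportions.

Protocol (C x K-CV with fixed seeds): a list of ``5*C`` seeds is split into
five batches of C; each seed drives one stratified K-fold CV, batch averages
give five run errors, and the mean of the five run GSIs is the reported score.
Model *structure* (per-class component count and covariance parameterization)
is selected once on the full data; per fold only the mixture parameters are
refitted on the training portion, warm-started from the full-data fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import gmda as _gmda
from .baselines import fit_lda
from .gmda import (
    PARAMETERIZATIONS,
    ClassMixture,
    DegenerateFitError,
    GmdaModel,
    em_fit,
    fit_gmda,
)
from .io import FeatureMatrix, LabelMap, align

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "CostSpec",
    "CvSpec",
    "RcvResult",
    "make_stratified_folds",
    "misclassification_rate",
    "total_prob_misclassification",
    "cv_error",
    "repeated_cv_error",
    "gsi",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class confusion counts: n_21 = class-1 objects misclassified as 2."""

    N1: int
    N2: int
    n_21: int
    n_12: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_21 <= self.N1 and 0 <= self.n_12 <= self.N2):
            raise ValueError(f"invalid confusion counts: {self}")


@dataclass(frozen=True)
class CostSpec:
    """Misclassification costs; c_12 = cost of calling a class-2 object class 1."""

    c_12: float = 1.0
    c_21: float = 1.0

    def __post_init__(self) -> None:
        if self.c_12 < 0 or self.c_21 < 0 or (self.c_12 == 0 and self.c_21 == 0):
            raise ValueError("costs must be non-negative and not both zero")


def _default_seeds() -> tuple[int, ...]:
    return tuple(range(1, 51))


@dataclass(frozen=True)
class CvSpec:
    """Configuration for repeated stratified cross-validation.

    ``seeds`` drives the fold partitions: one stratified K-fold CV per seed,
    averaged in batches of C (default: seeds 1..50, i.e. five 10 x 10 runs).
    ``em_seed`` seeds the k-means initializations of the structure selection.
    """

    K: int = 10
    C: int = 10
    seeds: tuple[int, ...] = field(default_factory=_default_seeds)
    classifier: str = "gmda"
    G_max: int = 2
    family: tuple[str, ...] = PARAMETERIZATIONS
    costs: CostSpec = field(default_factory=CostSpec)
    em_seed: int = 0
    tol: float = 1e-8
    max_iter: int = 500
    refit_structure_per_fold: bool = False

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.classifier not in ("gmda", "lda"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if len(self.seeds) % self.C != 0:
            raise ValueError(
                f"len(seeds)={len(self.seeds)} must be a multiple of C={self.C}"
            )

    @property
    def n_runs(self) -> int:
        return len(self.seeds) // self.C


@dataclass
class RcvResult:
    """Per-run errors/GSIs of a repeated CV, plus their mean."""

    run_errors: np.ndarray
    run_gsi: np.ndarray
    mean_gsi: float
    seed_errors: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def mean_error(self) -> float:
        return 1.0 - self.mean_gsi


def make_stratified_folds(labels: LabelMap, K: int, seed: int) -> dict[str, int]:
    """Assign each gene to one of K folds, preserving class proportions.

    Per class the fold sizes differ by at most one; deterministic given seed.
    """
    genes = list(labels.assignments)
    y = labels.y(genes)
    sizes = labels.class_sizes()
    small = [c for c, s in sizes.items() if s < K]
    if small:
        raise ValueError(
            f"class(es) {small} have fewer than K={K} genes; use a smaller K"
        )
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=int(seed) % (2**31))
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(genes), 1)), y)):
        for i in test_idx:
            assignment[genes[i]] = fold
    return assignment


def misclassification_rate(cc: ConfusionCounts, costs: CostSpec | None = None) -> float:
    """MER = (n_12 + n_21) / (N1 + N2); with costs, errors are cost-weighted."""
    total = cc.N1 + cc.N2
    if total == 0:
        raise ValueError("empty confusion matrix")
    if costs is None:
        costs = CostSpec()
    return (costs.c_21 * cc.n_21 + costs.c_12 * cc.n_12) / total


def total_prob_misclassification(
    p1: float, P_2given1: float, p2: float, P_1given2: float, costs: CostSpec | None = None
) -> float:
    """TPM = c_21 * p1 * P(2|1) + c_12 * p2 * P(1|2) (unit costs by default)."""
    for v in (p1, p2, P_2given1, P_1given2):
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if not np.isclose(p1 + p2, 1.0):
        raise ValueError("priors must sum to 1")
    if costs is None:
        costs = CostSpec()
    return costs.c_21 * p1 * P_2given1 + costs.c_12 * p2 * P_1given2


def gsi(error: float) -> float:
    """Group separation index: 1 - error."""
    if not 0.0 <= error <= 1.0:
        raise ValueError(f"error rate must lie in [0, 1], got {error}")
    return 1.0 - error


def _refit_class(
    X: np.ndarray, full_fit: ClassMixture, tol: float, max_iter: int
) -> ClassMixture:
    """Refit mixture parameters on training data under the fixed structure.

    Warm-started from the full-data estimates; falls back to a single
    component if the fold is too small or the constrained fit degenerates.
    """
    G = full_fit.n_components
    param = full_fit.parameterization
    if X.shape[0] >= G:
        try:
            return em_fit(
                X, G, param, tol=tol, max_iter=max_iter,
                init=(full_fit.weights, full_fit.means, full_fit.covariances),
            )
        except (DegenerateFitError, np.linalg.LinAlgError):
            pass
    logger.info("fold refit fell back to G=1 (%s)", param)
    return em_fit(X, 1, param, tol=tol, max_iter=max_iter)


def select_structure(data: FeatureMatrix, labels: LabelMap, spec: CvSpec) -> GmdaModel:
    """Fit the classifier once on the full data to fix per-class structure."""
    return fit_gmda(
        data, labels, G_max=spec.G_max, family=spec.family,
        seed=spec.em_seed, tol=spec.tol, max_iter=spec.max_iter,
    )


def _fold_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        N1=int(np.sum(y_true == 0)),
        N2=int(np.sum(y_true == 1)),
        n_21=int(np.sum((y_true == 0) & (y_pred == 1))),
        n_12=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def cv_error(
    data: FeatureMatrix,
    labels: LabelMap,
    spec: CvSpec,
    seed: int,
    structure: GmdaModel | None = None,
) -> float:
    """One stratified K-fold CV estimate of the misclassification error.

    For the mixture classifier, structure (per-class G, parameterization) is
    taken from ``structure`` or selected once on the full data; within each
    fold only the parameters are refitted on the training portion.  Fold MERs
    are averaged unweighted (stratified fold sizes differ by at most one).
    """
    data, labels = align(data, labels)
    labels.require_two_classes()
    fold_of = make_stratified_folds(labels, spec.K, seed)
    y = labels.y(data.gene_ids)
    folds = np.array([fold_of[g] for g in data.gene_ids])
    X = data.values

    if spec.classifier == "gmda" and structure is None and not spec.refit_structure_per_fold:
        structure = select_structure(data, labels, spec)

    fold_errors = np.empty(spec.K)
    for k in range(spec.K):
        train, test = folds != k, folds == k
        Xtr, ytr = X[train], y[train]
        if spec.classifier == "lda":
            sub = FeatureMatrix(
                [g for g, t in zip(data.gene_ids, train) if t], data.feature_ids, Xtr
            )
            model = fit_lda(sub, labels.subset(sub.gene_ids))
            y_pred = model.predict_index(X[test])
        else:
            mixtures = []
            for j in range(2):
                Xj = Xtr[ytr == j]
                if spec.refit_structure_per_fold:
                    mixtures.append(
                        _gmda.select_class_model(
                            Xj, G_max=spec.G_max, family=spec.family, tol=spec.tol,
                            seed=_gmda._derive_seed(spec.em_seed, k, j),
                            max_iter=spec.max_iter,
                        )
                    )
                else:
                    assert structure is not None
                    mixtures.append(
                        _refit_class(Xj, structure.class_mixtures[j], spec.tol, spec.max_iter)
                    )
            priors = np.array([np.sum(ytr == 0), np.sum(ytr == 1)], dtype=float)
            priors /= priors.sum()
            model = GmdaModel(tuple(labels.classes), tuple(mixtures), priors)
            y_pred = model.predict_index(X[test])
        fold_errors[k] = misclassification_rate(_fold_confusion(y[test], y_pred), spec.costs)
    return float(fold_errors.mean())


def repeated_cv_error(
    data: FeatureMatrix, labels: LabelMap, spec: CvSpec
) -> RcvResult:
    """Run one CV per seed, average seed batches of C into runs, report GSIs."""
    data, labels = align(data, labels)
    labels.require_two_classes()
    structure = None
    if spec.classifier == "gmda" and not spec.refit_structure_per_fold:
        structure = select_structure(data, labels, spec)
    seed_errors = np.array(
        [cv_error(data, labels, spec, seed, structure=structure) for seed in spec.seeds]
    )
    run_errors = seed_errors.reshape(spec.n_runs, spec.C).mean(axis=1)
    run_gsi = 1.0 - run_errors
    return RcvResult(run_errors, run_gsi, float(run_gsi.mean()), seed_errors)
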