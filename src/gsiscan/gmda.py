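"""Gaussian-mixture discriminant analysis (MclustDA-style classifier).

Each class density is a finite mixture of multivariate normals,

    f_j(y) = sum_k  tau_jk * N(y | mu_jk, Sigma_jk),        k = 1..G_j,

fitted per class by maximum likelihood via EM.  The number of components G_j
and the covariance parameterization are selected per class by BIC (in the
larger-is-better convention ``2*loglik - n_params*log(n)``, as in mclust).
Classification is by the Bayes posterior

    P(y in class j) = tau_j f_j(y) / sum_k tau_k f_k(y),

with class priors tau_j equal to the training class proportions.

Six covariance parameterizations are supported: spherical / diagonal / full
crossed with equal / varying across components (mclust codes EII, VII, EEI,
VVI, EEE, VVV).  The "-equal" constraint ties the covariance across the
components of a class; in the single-component all-equal configuration
(``G_max=1`` with only equal variants) it ties the covariance across the two
classes as well, so ``family={"full-equal"}, G_max=1`` is exactly LDA and the
diagonal/spherical analogues are diagonal/spherical LDA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .io import FeatureMatrix, LabelMap, align

__all__ = [
    "PARAMETERIZATIONS",
    "MCLUST_NAMES",
    "MixtureComponent",
    "ClassMixture",
    "GmdaModel",
    "DegenerateFitError",
    "n_free_params",
    "em_fit",
    "bic_score",
    "select_class_model",
    "fit_gmda",
    "class_posterior",
]

#: Covariance parameterizations, in tie-break order.
PARAMETERIZATIONS: tuple[str, ...] = (
    "spherical-equal",
    "spherical-varying",
    "diagonal-equal",
    "diagonal-varying",
    "full-equal",
    "full-varying",
)

#: mclust model codes for the six parameterizations (used by the R cross-check).
MCLUST_NAMES: dict[str, str] = {
    "spherical-equal": "EII",
    "spherical-varying": "VII",
    "diagonal-equal": "EEI",
    "diagonal-varying": "VVI",
    "full-equal": "EEE",
    "full-varying": "VVV",
}

_RIDGE_FACTOR = 1e-6


class DegenerateFitError(RuntimeError):
    """EM collapsed to a degenerate solution that regularization could not rescue."""


def n_free_params(parameterization: str, G: int, d: int) -> int:
    """Free parameters of a G-component mixture in d dimensions.

    Weights contribute G-1, means G*d, and the covariance block depends on the
    parameterization (e.g. full-varying, d=2, G=2: 1 + 4 + 6 = 11).
    """
    cov = {
        "spherical-equal": 1,
        "spherical-varying": G,
        "diagonal-equal": d,
        "diagonal-varying": G * d,
        "full-equal": d * (d + 1) // 2,
        "full-varying": G * d * (d + 1) // 2,
    }[parameterization]
    return (G - 1) + G * d + cov


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: np.ndarray
    covariance: np.ndarray


@dataclass
class ClassMixture:
    """A fitted per-class Gaussian mixture."""

    components: list[MixtureComponent]
    parameterization: str
    log_likelihood: float
    bic: float
    n_params: int
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.stack([c.mean for c in self.components])

    @property
    def covariances(self) -> np.ndarray:
        return np.stack([c.covariance for c in self.components])

    def logpdf(self, X: np.ndarray) -> np.ndarray:
        """Mixture log density at each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        parts = np.stack(
            [np.log(c.weight) + _mvn_logpdf(X, c.mean, c.covariance) for c in self.components]
        )
        return logsumexp(parts, axis=0)


def _mvn_logpdf(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    diff = X - mean
    sol = np.linalg.solve(L, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _batched_log_densities(X: np.ndarray, weights, means, covs) -> np.ndarray:
    """n x G matrix of log(tau_k) + log N(x | mu_k, Sigma_k), batched over k."""
    n, d = X.shape
    L = np.linalg.cholesky(covs)  # (G, d, d); raises LinAlgError if not SPD
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    prec = np.linalg.inv(covs)
    diff = X[None, :, :] - means[:, None, :]  # (G, n, d)
    maha = np.einsum("gni,gij,gnj->gn", diff, prec, diff)
    logw = np.log(np.maximum(weights, np.finfo(float).tiny))
    out = logw[:, None] - 0.5 * (d * np.log(2.0 * np.pi) + logdet[:, None] + maha)
    return out.T


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    m = a.max(axis=1)
    return m + np.log(np.sum(np.exp(a - m[:, None]), axis=1))


def _ensure_spd(cov: np.ndarray, data_scale: float) -> np.ndarray:
    """Return an SPD version of cov, adding a small ridge if necessary."""
    cov = 0.5 * (cov + cov.T)
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError:
        pass
    ridge = _RIDGE_FACTOR * max(data_scale, np.finfo(float).tiny)
    cov = cov + ridge * np.eye(cov.shape[0])
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError as err:
        raise DegenerateFitError("covariance not positive-definite even after ridge") from err


def _ensure_spd_batch(covs: np.ndarray, data_scale: float) -> np.ndarray:
    """SPD-check a (G, d, d) stack, adding a small shared ridge if necessary."""
    covs = 0.5 * (covs + np.swapaxes(covs, 1, 2))
    try:
        np.linalg.cholesky(covs)
        return covs
    except np.linalg.LinAlgError:
        pass
    ridge = _RIDGE_FACTOR * max(data_scale, np.finfo(float).tiny)
    covs = covs + ridge * np.eye(covs.shape[1])
    try:
        np.linalg.cholesky(covs)
        return covs
    except np.linalg.LinAlgError as err:
        raise DegenerateFitError("covariance not positive-definite even after ridge") from err


def _mstep_covariances(
    X: np.ndarray, resp: np.ndarray, means: np.ndarray, parameterization: str, data_scale: float
) -> np.ndarray:
    """Constrained ML covariance update; returns one d x d matrix per component."""
    n, d = X.shape
    G = resp.shape[1]
    Nk = resp.sum(axis=0)
    diff = X[None, :, :] - means[:, None, :]  # (G, n, d)
    scatters = np.einsum("ng,gni,gnj->gij", resp, diff, diff)
    kind, tie = parameterization.split("-")
    eye = np.eye(d)
    if tie == "equal":
        pooled = scatters.sum(axis=0) / n
        if kind == "full":
            cov = pooled
        elif kind == "diagonal":
            cov = np.diag(np.diag(pooled))
        else:  # spherical
            cov = (np.trace(pooled) / d) * eye
        cov = _ensure_spd(cov, data_scale)
        return np.broadcast_to(cov, (G, d, d)).copy()
    Sk = scatters / np.maximum(Nk, np.finfo(float).tiny)[:, None, None]
    if kind == "full":
        covs = Sk
    elif kind == "diagonal":
        covs = np.zeros_like(Sk)
        idx = np.arange(d)
        covs[:, idx, idx] = Sk[:, idx, idx]
    else:
        var = np.trace(Sk, axis1=1, axis2=2) / d
        covs = var[:, None, None] * eye
    return _ensure_spd_batch(covs, data_scale)


def em_fit(
    points: np.ndarray,
    G: int,
    parameterization: str,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> ClassMixture:
    """Fit a G-component constrained Gaussian mixture to one class by EM.

    Initialization is k-means (deterministic given ``seed``) unless ``init``
    supplies warm-start ``(weights, means, covariances)``.  The observed-data
    log-likelihood is non-decreasing over iterations; the trace is kept on the
    returned :class:`ClassMixture` as ``loglik_trace``.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = X.shape
    if parameterization not in PARAMETERIZATIONS:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    if G < 1:
        raise ValueError("G must be >= 1")
    if n < G:
        raise ValueError(f"need at least G={G} points, got n={n}")
    data_scale = float(np.mean(np.var(X, axis=0))) if n > 1 else 1.0
    if data_scale <= 0:
        data_scale = 1.0

    if init is not None:
        weights = np.asarray(init[0], dtype=float).copy()
        means = np.asarray(init[1], dtype=float).copy()
        covs = np.asarray(init[2], dtype=float).copy()
        if len(weights) != G:
            raise ValueError("warm start has wrong number of components")
    else:
        if G == 1:
            hard = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=G, n_init=1, random_state=int(seed) % (2**31), max_iter=100)
            hard = km.fit_predict(X)
        resp = np.zeros((n, G))
        resp[np.arange(n), hard] = 1.0
        Nk = resp.sum(axis=0)
        if np.any(Nk == 0):  # k-means left a component empty; seed it with one point
            for k in np.flatnonzero(Nk == 0):
                resp[np.argmax(resp.sum(axis=1)), :] = 0.0
                resp[k % n, k] = 1.0
            Nk = resp.sum(axis=0)
        weights = Nk / n
        means = (resp.T @ X) / Nk[:, None]
        covs = _mstep_covariances(X, resp, means, parameterization, data_scale)

    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        try:
            logdens = _batched_log_densities(X, weights, means, covs)
        except np.linalg.LinAlgError as err:
            raise DegenerateFitError(f"covariance degenerate (G={G}, {parameterization})") from err
        lse = _logsumexp_rows(logdens)
        ll = float(np.sum(lse))
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= tol * (1.0 + abs(ll)):
            break
        prev = ll
        resp = np.exp(logdens - lse[:, None])
        Nk = resp.sum(axis=0)
        if np.any(Nk < 1e-10):
            raise DegenerateFitError(
                f"component collapsed to zero weight (G={G}, {parameterization})"
            )
        weights = Nk / n
        means = (resp.T @ X) / Nk[:, None]
        covs = _mstep_covariances(X, resp, means, parameterization, data_scale)

    ll = trace[-1]
    k = n_free_params(parameterization, G, d)
    comps = [
        MixtureComponent(float(w), m.copy(), c.copy()) for w, m, c in zip(weights, means, covs)
    ]
    return ClassMixture(comps, parameterization, ll, bic_score(ll, k, n), k, trace)


def bic_score(log_likelihood: float, n_params: int, n: int) -> float:
    """BIC in the larger-is-better (mclust) convention: 2*loglik - k*log(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 2.0 * log_likelihood - n_params * np.log(n)


def select_class_model(
    points: np.ndarray,
    G_max: int = 2,
    family: Sequence[str] = PARAMETERIZATIONS,
    tol: float = 1e-8,
    seed: int = 0,
    max_iter: int = 500,
) -> ClassMixture:
    """Fit every (G, parameterization) pair, 1 <= G <= G_max, and return the best BIC.

    Ties break toward smaller G, then toward earlier entries of ``family``.
    """
    family = tuple(family)
    if not family:
        raise ValueError("family must be non-empty")
    if G_max < 1:
        raise ValueError("G_max must be >= 1")
    X = np.atleast_2d(np.asarray(points, dtype=float))
    best: ClassMixture | None = None
    errors: list[str] = []
    for G in range(1, G_max + 1):
        if G > X.shape[0]:
            break
        for p_idx, param in enumerate(family):
            em_seed = _derive_seed(seed, G, p_idx)
            try:
                fit = em_fit(X, G, param, tol=tol, max_iter=max_iter, seed=em_seed)
            except (DegenerateFitError, np.linalg.LinAlgError) as err:
                errors.append(f"G={G} {param}: {err}")
                continue
            if best is None or fit.bic > best.bic:
                best = fit
    if best is None:
        raise DegenerateFitError("all candidate fits degenerate: " + "; ".join(errors))
    return best


def _derive_seed(master: int, *keys: int) -> int:
    ss = np.random.SeedSequence(int(master) % (2**31), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class GmdaModel:
    """Two-class mixture discriminant classifier."""

    class_labels: tuple[str, str]
    class_mixtures: tuple[ClassMixture, ClassMixture]
    class_priors: np.ndarray

    def __post_init__(self) -> None:
        self.class_priors = np.asarray(self.class_priors, dtype=float)
        if not np.isclose(self.class_priors.sum(), 1.0):
            raise ValueError("class priors must sum to 1")

    @property
    def n_features(self) -> int:
        return self.class_mixtures[0].components[0].mean.shape[0]

    def log_joint(self, X: np.ndarray) -> np.ndarray:
        """n x 2 matrix of log(prior_j) + log f_j(x)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        with np.errstate(divide="ignore"):
            lp = np.log(self.class_priors)
        return np.column_stack([lp[j] + self.class_mixtures[j].logpdf(X) for j in range(2)])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        lj = self.log_joint(X)
        # a prior of exactly 0 yields -inf which normalizes to posterior 0
        lj = np.where(np.isneginf(lj), -1e300, lj)
        return np.exp(lj - logsumexp(lj, axis=1, keepdims=True))

    def predict_index(self, X: np.ndarray) -> np.ndarray:
        """Class indices; posterior ties resolve to the first class in label order."""
        post = self.predict_proba(X)
        return (post[:, 1] > post[:, 0]).astype(int)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array(self.class_labels, dtype=object)[self.predict_index(X)]

    def to_json(self) -> str:
        doc = {
            "class_labels": list(self.class_labels),
            "class_priors": self.class_priors.tolist(),
            "classes": [
                {
                    "parameterization": cm.parameterization,
                    "log_likelihood": cm.log_likelihood,
                    "bic": cm.bic,
                    "n_params": cm.n_params,
                    "components": [
                        {
                            "weight": c.weight,
                            "mean": c.mean.tolist(),
                            "covariance": c.covariance.tolist(),
                        }
                        for c in cm.components
                    ],
                }
                for cm in self.class_mixtures
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GmdaModel":
        doc = json.loads(text)
        mixtures = []
        for cm in doc["classes"]:
            comps = [
                MixtureComponent(
                    float(c["weight"]), np.array(c["mean"], float), np.array(c["covariance"], float)
                )
                for c in cm["components"]
            ]
            mixtures.append(
                ClassMixture(
                    comps,
                    cm["parameterization"],
                    float(cm["log_likelihood"]),
                    float(cm["bic"]),
                    int(cm["n_params"]),
                )
            )
        return cls(tuple(doc["class_labels"]), tuple(mixtures), np.array(doc["class_priors"]))


def _fit_pooled_single_component(
    Xs: list[np.ndarray], family: Sequence[str]
) -> list[ClassMixture]:
    """All-equal, G=1 path: one covariance shared across both classes (LDA family).

    Selection among the requested equal variants is by joint BIC over the
    pooled likelihood.
    """
    d = Xs[0].shape[1]
    n_total = sum(X.shape[0] for X in Xs)
    means = [X.mean(axis=0) for X in Xs]
    pooled = sum(
        (X - m).T @ (X - m) for X, m in zip(Xs, means)
    ) / n_total
    data_scale = float(np.trace(pooled) / d) or 1.0
    best = None
    for param in family:
        kind = param.split("-")[0]
        if kind == "full":
            cov = pooled
            k_cov = d * (d + 1) // 2
        elif kind == "diagonal":
            cov = np.diag(np.diag(pooled))
            k_cov = d
        else:
            cov = (np.trace(pooled) / d) * np.eye(d)
            k_cov = 1
        cov = _ensure_spd(cov, data_scale)
        lls = [float(np.sum(_mvn_logpdf(X, m, cov))) for X, m in zip(Xs, means)]
        k_total = 2 * d + k_cov
        joint_bic = bic_score(sum(lls), k_total, n_total)
        if best is None or joint_bic > best[0]:
            best = (joint_bic, param, cov, lls, k_total)
    assert best is not None
    joint_bic, param, cov, lls, k_total = best
    return [
        ClassMixture(
            [MixtureComponent(1.0, m.copy(), cov.copy())],
            param,
            ll,
            joint_bic,
            k_total,
            [ll],
        )
        for m, ll in zip(means, lls)
    ]


def fit_gmda(
    data: FeatureMatrix,
    labels: LabelMap,
    G_max: int = 2,
    family: Sequence[str] = PARAMETERIZATIONS,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GmdaModel:
    """Fit the two-class mixture discriminant model.

    Each class is fitted independently by :func:`select_class_model`; class
    priors are the training class proportions.  When ``G_max == 1`` and the
    family contains only "-equal" variants, the covariance is pooled across
    classes (the LDA family; see module docstring).
    """
    data, labels = align(data, labels)
    labels.require_two_classes()
    family = tuple(family)
    y = labels.y(data.gene_ids)
    d = data.n_features
    Xs = [data.values[y == j] for j in range(2)]
    for lab, X in zip(labels.classes, Xs):
        if X.shape[0] < 2 * d:
            raise ValueError(
                f"class {lab!r} has {X.shape[0]} genes; need at least 2*d = {2 * d} "
                f"to fit a {d}-feature mixture"
            )
    priors = np.array([X.shape[0] for X in Xs], dtype=float)
    priors /= priors.sum()
    if G_max == 1 and all(p.endswith("-equal") for p in family):
        mixtures = _fit_pooled_single_component(Xs, family)
    else:
        mixtures = [
            select_class_model(
                X, G_max=G_max, family=family, tol=tol,
                seed=_derive_seed(seed, j), max_iter=max_iter,
            )
            for j, X in enumerate(Xs)
        ]
    return GmdaModel(tuple(labels.classes), tuple(mixtures), priors)


def class_posterior(model: GmdaModel, point: np.ndarray) -> tuple[float, float]:
    """Posterior class probabilities at one point (sums to 1)."""
    post = model.predict_proba(np.atleast_2d(point))[0]
    return float(post[0]), float(post[1])
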