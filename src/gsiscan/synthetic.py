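"""Synthetic two-class log2-fold-change data with a known Bayes-error oracle.

The generator emulates the geometry of multi-experiment differential
expression profiles: most genes sit in a dense cluster near the origin
(non-DE under both contrasts of an informative pair), each class adds its own
displaced Gaussian component(s) on the informative features, and the
remaining features are class-independent noise.  Because the true class
densities are known, the Bayes-optimal misclassification probability can be
estimated by Monte Carlo and used as ground truth for the CV machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import logsumexp

from .cv import CvSpec, repeated_cv_error
from .io import FeatureMatrix, LabelMap, subset_columns

__all__ = [
    "ComponentSpec",
    "SyntheticSpec",
    "BayesOracle",
    "default_feature_ids",
    "default_pathway_spec",
    "spherical_two_class_spec",
    "generate_two_class",
    "bayes_error_mc",
    "sample_size_study",
    "spec_to_yaml",
    "spec_from_yaml",
]


def default_feature_ids() -> tuple[str, ...]:
    """23 contrast ids laid out as five experiments (1 + 3 + 2 + 8 + 9 contrasts)."""
    counts = {1: 1, 2: 3, 3: 2, 4: 8, 5: 9}
    return tuple(f"{e}-{j}" for e, c in counts.items() for j in range(1, c + 1))


@dataclass(frozen=True)
class ComponentSpec:
    """One Gaussian component on the informative features."""

    weight: float
    mean: tuple[float, ...]
    covariance: tuple[tuple[float, ...], ...]

    def mean_arr(self) -> np.ndarray:
        return np.asarray(self.mean, dtype=float)

    def cov_arr(self) -> np.ndarray:
        return np.asarray(self.covariance, dtype=float)


def _iso(var: float, k: int) -> tuple[tuple[float, ...], ...]:
    return tuple(tuple(float(var) if i == j else 0.0 for j in range(k)) for i in range(k))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration for a two-class log2-FC matrix.

    ``components`` maps class label -> Gaussian mixture on the informative
    features; all other features are independent N(0, noise_sd^2) in both
    classes, so only the informative subset carries group information.
    """

    classes: tuple[str, str]
    components: dict[str, tuple[ComponentSpec, ...]]
    n_per_class: tuple[int, int]
    feature_ids: tuple[str, ...]
    informative_features: tuple[str, ...]
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) != 2:
            raise ValueError("exactly two classes required")
        if set(self.components) != set(self.classes):
            raise ValueError("components must be keyed by the two class labels")
        for lab, comps in self.components.items():
            w = sum(c.weight for c in comps)
            if not np.isclose(w, 1.0):
                raise ValueError(f"class {lab!r} component weights sum to {w}, not 1")
            for c in comps:
                cov = c.cov_arr()
                if cov.shape != (len(self.informative_features),) * 2:
                    raise ValueError("component covariance has wrong shape")
                if np.any(np.linalg.eigvalsh(cov) <= 0):
                    raise ValueError("component covariance must be SPD")
        unknown = set(self.informative_features) - set(self.feature_ids)
        if unknown:
            raise ValueError(f"informative features not in feature_ids: {unknown}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def priors(self) -> np.ndarray:
        n = np.asarray(self.n_per_class, dtype=float)
        return n / n.sum()


def default_pathway_spec(seed: int = 0) -> SyntheticSpec:
    """Two-pathway fixture mirroring the published two-experiment geometry.

    Class JA (n=48) mixes a near-origin component with one centered at
    (2.276, 1.663); class ET (n=86) is a single component centered at
    (0.537, 0.406).  Those centers and the class sizes are reported values;
    the mixture weights (0.6/0.4), component covariances (0.25*I, 0.5*I,
    0.5*I) and the 0.5 noise sd are declared fixture constants chosen to
    match the published scatterplot geometry, not reported numbers.
    """
    comps = {
        "JA": (
            ComponentSpec(0.6, (0.0, 0.0), _iso(0.25, 2)),
            ComponentSpec(0.4, (2.276, 1.663), _iso(0.5, 2)),
        ),
        "ET": (ComponentSpec(1.0, (0.537, 0.406), _iso(0.5, 2)),),
    }
    return SyntheticSpec(
        classes=("JA", "ET"),
        components=comps,
        n_per_class=(48, 86),
        feature_ids=default_feature_ids(),
        informative_features=("4-7", "4-8"),
        noise_sd=0.5,
        seed=seed,
    )


def spherical_two_class_spec(
    delta: float = 2.0,
    sigma: float = 1.0,
    n_per_class: tuple[int, int] = (500, 500),
    n_features: int = 2,
    seed: int = 0,
) -> SyntheticSpec:
    """Equal-covariance spherical classes separated by ``delta`` along axis 1.

    The Bayes error has the closed form Phi(-delta / (2*sigma)) under equal
    priors, making this the reference configuration for error-recovery checks.
    """
    ids = tuple(f"f{j + 1}" for j in range(n_features))
    comps = {
        "A": (ComponentSpec(1.0, (0.0, 0.0), _iso(sigma**2, 2)),),
        "B": (ComponentSpec(1.0, (float(delta), 0.0), _iso(sigma**2, 2)),),
    }
    return SyntheticSpec(
        classes=("A", "B"),
        components=comps,
        n_per_class=n_per_class,
        feature_ids=ids,
        informative_features=ids[:2],
        noise_sd=0.5,
        seed=seed,
    )


def generate_two_class(spec: SyntheticSpec) -> tuple[FeatureMatrix, LabelMap]:
    """Draw a (sum n_per_class) x n_features matrix plus labels; seed-deterministic."""
    rng = np.random.default_rng(int(spec.seed) % (2**31))
    info_idx = [spec.feature_ids.index(f) for f in spec.informative_features]
    rows, genes, assignment = [], [], {}
    for lab, n in zip(spec.classes, spec.n_per_class):
        comps = spec.components[lab]
        weights = np.array([c.weight for c in comps])
        which = rng.choice(len(comps), size=n, p=weights)
        block = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
        for i, k in enumerate(which):
            c = comps[k]
            block[i, info_idx] = rng.multivariate_normal(c.mean_arr(), c.cov_arr())
        for i in range(n):
            g = f"{lab}_{i + 1:04d}"
            genes.append(g)
            assignment[g] = lab
        rows.append(block)
    fm = FeatureMatrix(genes, list(spec.feature_ids), np.vstack(rows))
    return fm, LabelMap(assignment, classes=list(spec.classes))


def _class_log_density(
    spec: SyntheticSpec, label: str, X: np.ndarray, feat_idx: Sequence[int]
) -> np.ndarray:
    """True log density of one class marginalized to the chosen features."""
    info_pos = {spec.feature_ids.index(f): i for i, f in enumerate(spec.informative_features)}
    parts = []
    for c in spec.components[label]:
        mean = np.zeros(len(feat_idx))
        cov = np.eye(len(feat_idx)) * spec.noise_sd**2
        cm, cc = c.mean_arr(), c.cov_arr()
        sel = [(a, info_pos[j]) for a, j in enumerate(feat_idx) if j in info_pos]
        for a, i in sel:
            mean[a] = cm[i]
            for b, k in sel:
                cov[a, b] = cc[i, k]
        L = np.linalg.cholesky(cov)
        diff = X - mean
        sol = np.linalg.solve(L, diff.T)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        lp = -0.5 * (len(feat_idx) * np.log(2 * np.pi) + logdet + np.sum(sol**2, axis=0))
        parts.append(np.log(c.weight) + lp)
    return logsumexp(np.stack(parts), axis=0)


def spec_to_yaml(spec: SyntheticSpec) -> str:
    doc = {
        "classes": list(spec.classes),
        "n_per_class": list(spec.n_per_class),
        "feature_ids": list(spec.feature_ids),
        "informative_features": list(spec.informative_features),
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "components": {
            lab: [
                {
                    "weight": float(c.weight),
                    "mean": [float(x) for x in c.mean],
                    "covariance": [[float(x) for x in row] for row in c.covariance],
                }
                for c in comps
            ]
            for lab, comps in spec.components.items()
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_yaml(text: str) -> SyntheticSpec:
    doc = yaml.safe_load(text)
    comps = {
        lab: tuple(
            ComponentSpec(
                float(c["weight"]),
                tuple(float(x) for x in c["mean"]),
                tuple(tuple(float(x) for x in row) for row in c["covariance"]),
            )
            for c in entries
        )
        for lab, entries in doc["components"].items()
    }
    return SyntheticSpec(
        classes=tuple(doc["classes"]),
        components=comps,
        n_per_class=tuple(int(n) for n in doc["n_per_class"]),
        feature_ids=tuple(doc["feature_ids"]),
        informative_features=tuple(doc["informative_features"]),
        noise_sd=float(doc.get("noise_sd", 0.5)),
        seed=int(doc.get("seed", 0)),
    )


@dataclass(frozen=True)
class BayesOracle:
    """Monte-Carlo estimate of the Bayes-rule total misclassification probability."""

    error: float
    mc_n: int
    mc_se: float


def bayes_error_mc(
    spec: SyntheticSpec,
    features: Sequence[str] | None = None,
    mc_n: int = 100_000,
    seed: int = 0,
) -> BayesOracle:
    """Estimate the optimal-rule TPM using the true densities and priors.

    Draws mc_n labeled points, classifies each with the true posterior, and
    reports the misclassification fraction with its binomial standard error.
    """
    if mc_n < 10_000:
        raise ValueError("mc_n must be at least 10^4 for a stable oracle")
    feats = list(features) if features is not None else list(spec.informative_features)
    feat_idx = [spec.feature_ids.index(f) for f in feats]
    rng = np.random.default_rng(int(seed) % (2**31))
    priors = spec.priors()
    y = rng.choice(2, size=mc_n, p=priors)
    # sample the marginal over the chosen features directly
    X = np.empty((mc_n, len(feats)))
    info_pos = {spec.feature_ids.index(f): i for i, f in enumerate(spec.informative_features)}
    for j, lab in enumerate(spec.classes):
        mask = y == j
        n = int(mask.sum())
        comps = spec.components[lab]
        weights = np.array([c.weight for c in comps])
        which = rng.choice(len(comps), size=n, p=weights)
        block = rng.normal(0.0, spec.noise_sd, size=(n, len(feats)))
        sel = [(a, info_pos[fi]) for a, fi in enumerate(feat_idx) if fi in info_pos]
        if sel:
            for i, k in enumerate(which):
                c = comps[k]
                draw = rng.multivariate_normal(c.mean_arr(), c.cov_arr())
                for a, ip in sel:
                    block[i, a] = draw[ip]
        X[mask] = block
    log_post = np.column_stack(
        [
            np.log(priors[j]) + _class_log_density(spec, lab, X, feat_idx)
            for j, lab in enumerate(spec.classes)
        ]
    )
    pred = (log_post[:, 1] > log_post[:, 0]).astype(int)
    err = float(np.mean(pred != y))
    se = float(np.sqrt(max(err * (1 - err), 1e-12) / mc_n))
    return BayesOracle(err, mc_n, se)


def sample_size_study(
    spec: SyntheticSpec,
    n_grid: Sequence[int],
    reps: int,
    cv_spec: CvSpec,
    features: Sequence[str] | None = None,
    mc_n: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bias and spread of the repeated-CV GSI as per-class sample size grows.

    For each n, regenerates ``reps`` datasets with n genes per class, runs the
    repeated-CV GSI on the chosen features, and reports the mean GSI, its bias
    against the Bayes oracle (1 - Bayes error) and the SD across repetitions
    (NaN when reps == 1).
    """
    if list(n_grid) != sorted(n_grid):
        raise ValueError("n_grid must be increasing")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    feats = list(features) if features is not None else list(spec.informative_features)
    oracle = bayes_error_mc(spec, feats, mc_n=mc_n, seed=seed)
    oracle_gsi = 1.0 - oracle.error
    rows = []
    for gi, n in enumerate(n_grid):
        gsis = np.empty(reps)
        for r in range(reps):
            rep_seed = int(
                np.random.SeedSequence(int(seed) % (2**31), spawn_key=(gi, r))
                .generate_state(1)[0] % (2**31)
            )
            s = replace(spec, n_per_class=(int(n), int(n)), seed=rep_seed)
            fm, labels = generate_two_class(s)
            gsis[r] = repeated_cv_error(subset_columns(fm, feats), labels, cv_spec).mean_gsi
        rows.append(
            {
                "n": int(n),
                "mean_gsi": float(gsis.mean()),
                "bias": float(gsis.mean() - oracle_gsi),
                "sd": float(gsis.std(ddof=1)) if reps > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
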