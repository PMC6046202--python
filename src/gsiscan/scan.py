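"""Exhaustive enumeration and GSI ranking of all M-feature subsets.

For p features and subset size M (2, 3 or 4) every one of the C(p, M)
subsets is scored by repeated stratified CV and ranked by its mean GSI.
Ties are detected at printed precision (3 decimals by default, matching how
GSI tables are reported) and share the minimum rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from .cv import CvSpec, RcvResult, repeated_cv_error
from .io import FeatureMatrix, LabelMap, align, subset_columns

logger = logging.getLogger(__name__)

__all__ = ["SubsetScore", "enumerate_subsets", "assign_ranks", "scan_and_rank"]


@dataclass
class SubsetScore:
    """GSI record for one candidate feature subset."""

    features: tuple[str, ...]
    run_gsi: np.ndarray | None
    mean_gsi: float
    rank: int | None = None
    tied: bool = False
    failed: bool = False
    failure: str | None = None


def enumerate_subsets(feature_ids: Sequence[str], M: int) -> list[tuple[str, ...]]:
    """All M-subsets of features as sorted tuples, in lexicographic order."""
    ids = sorted(map(str, feature_ids))
    if len(set(ids)) != len(ids):
        raise ValueError("feature ids must be unique")
    if not 1 <= M <= len(ids):
        raise ValueError(f"M must be in [1, {len(ids)}], got {M}")
    return list(combinations(ids, M))


def assign_ranks(scores: Sequence[float]) -> tuple[list[int], list[bool]]:
    """Descending min-rank ("1224") ranking with tie flags.

    Each value's rank is 1 + the count of strictly greater values; equal
    values share that rank and are flagged tied.
    """
    if len(scores) == 0:
        raise ValueError("no scores to rank")
    arr = np.asarray(scores, dtype=float)
    ranks = [int(1 + np.sum(arr > v)) for v in arr]
    tied = [bool(np.sum(arr == v) > 1) for v in arr]
    return ranks, tied


def _score_one(
    fm: FeatureMatrix, labels: LabelMap, features: tuple[str, ...], spec: CvSpec
) -> SubsetScore:
    try:
        res: RcvResult = repeated_cv_error(subset_columns(fm, features), labels, spec)
    except Exception as err:  # recorded, not silently dropped
        logger.warning("subset %s failed: %s", "+".join(features), err)
        return SubsetScore(features, None, float("nan"), failed=True, failure=str(err))
    return SubsetScore(features, res.run_gsi, res.mean_gsi)


def scan_and_rank(
    fm: FeatureMatrix,
    labels: LabelMap,
    M: int,
    spec: CvSpec,
    tie_decimals: int | None = 3,
    n_jobs: int = 1,
) -> list[SubsetScore]:
    """Score every M-subset of features by repeated-CV GSI and rank them.

    Subsets are identified by sorted feature ids, so the result does not
    depend on the column order of the input matrix; with the same spec the
    ranking is identical regardless of ``n_jobs``.  ``tie_decimals`` rounds
    mean GSIs before ranking/tie detection (None compares exact floats).
    Failed subsets are flagged and excluded from ranking.
    """
    fm, labels = align(fm, labels)
    labels.require_two_classes()
    subsets = enumerate_subsets(fm.feature_ids, M)
    if n_jobs != 1:
        scores = Parallel(n_jobs=n_jobs)(
            delayed(_score_one)(fm, labels, s, spec) for s in subsets
        )
    else:
        scores = [_score_one(fm, labels, s, spec) for s in subsets]
    ok = [s for s in scores if not s.failed]
    if ok:
        vals = [s.mean_gsi for s in ok]
        if tie_decimals is not None:
            vals = [round(v, tie_decimals) for v in vals]
        ranks, tied = assign_ranks(vals)
        for s, r, t in zip(ok, ranks, tied):
            s.rank, s.tied = r, t
    n_failed = len(scores) - len(ok)
    if n_failed:
        logger.warning("scan: %d of %d subsets failed", n_failed, len(scores))
    return sorted(
        scores,
        key=lambda s: (s.failed, s.rank if s.rank is not None else np.inf, s.features),
    )
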