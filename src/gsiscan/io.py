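"""Reading, writing and subsetting log2-fold-change feature matrices and gene labels.

The central container is :class:`FeatureMatrix`: genes in rows, treatment-control
contrasts ("experiment-contrast", e.g. ``"4-7"``) in columns, values on the base-2
log scale.  :class:`LabelMap` carries the gene -> pathway/class assignment used for
the two-group separation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "LabelMap",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_labels",
    "write_labels",
    "filter_low_fold_change",
    "subset_columns",
    "align",
    "ranking_table",
    "write_ranking_table",
]


class DataValidationError(ValueError):
    """Input violates a container invariant (duplicates, non-finite values, ...)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise DataValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class FeatureMatrix:
    """Genes x features matrix of log2 fold changes.

    Parameters
    ----------
    gene_ids : unique row identifiers.
    feature_ids : unique column identifiers in "experiment-contrast" form.
    values : float array of shape ``(len(gene_ids), len(feature_ids))``; all finite.
    """

    gene_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataValidationError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.feature_ids)):
            raise DataValidationError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.feature_ids)} features"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise DataValidationError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"feature {self.feature_ids[j]!r} (missing values are not supported)"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(dtype=float))

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


@dataclass
class LabelMap:
    """Gene -> class assignment with classes kept in first-appearance order."""

    assignments: dict[str, str]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        observed: list[str] = []
        for c in self.assignments.values():
            if c not in observed:
                observed.append(c)
        if not self.classes:
            self.classes = observed
        else:
            missing = [c for c in observed if c not in self.classes]
            if missing:
                raise DataValidationError(f"labels use classes not listed: {missing}")

    def __len__(self) -> int:
        return len(self.assignments)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_sizes(self) -> dict[str, int]:
        sizes = {c: 0 for c in self.classes}
        for c in self.assignments.values():
            sizes[c] += 1
        return sizes

    def y(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Integer class indices (order of :attr:`classes`) for the given genes."""
        idx = {c: k for k, c in enumerate(self.classes)}
        return np.array([idx[self.assignments[g]] for g in gene_ids], dtype=int)

    def subset(self, gene_ids: Iterable[str]) -> "LabelMap":
        sub = {g: self.assignments[g] for g in gene_ids if g in self.assignments}
        return LabelMap(sub, classes=[c for c in self.classes if c in set(sub.values())] or self.classes)

    def require_two_classes(self) -> None:
        if self.n_classes != 2:
            raise DataValidationError(
                f"exactly 2 classes are required for group-separation analysis, "
                f"got {self.n_classes}: {self.classes}"
            )


def _delimiter_for(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


def read_feature_matrix(path: str | Path, delimiter: str | None = None) -> FeatureMatrix:
    """Read a delimited matrix: header row of feature ids, first column gene ids.

    The delimiter is auto-detected from the extension (``.csv`` -> comma,
    otherwise tab) unless given explicitly.
    """
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataValidationError(f"{path}: empty feature matrix")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for j, col in enumerate(df.columns):
        for i, gene in enumerate(df.index):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise DataValidationError(
                    f"{path}: non-numeric cell at gene {gene!r}, feature {col!r}: {raw[i, j]!r}"
                ) from None
    return FeatureMatrix(list(df.index), list(df.columns), values)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path, delimiter: str | None = None,
                         float_format: str = "%.10g") -> None:
    sep = _delimiter_for(path, delimiter)
    fm.to_frame().to_csv(path, sep=sep, index_label="gene", float_format=float_format)


def read_labels(path: str | Path, delimiter: str | None = None) -> LabelMap:
    """Read a two-column gene_id, class file (header optional, detected)."""
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[0] == 0:
        raise DataValidationError(f"{path}: empty label file")
    if df.shape[1] < 2:
        raise DataValidationError(f"{path}: expected two columns (gene_id, class)")
    # Tolerate a header line such as "gene<TAB>class".
    first = str(df.iloc[0, 0]).lower()
    if first in {"gene", "gene_id", "id"}:
        df = df.iloc[1:]
        if df.shape[0] == 0:
            raise DataValidationError(f"{path}: label file has a header but no rows")
    assignments: dict[str, str] = {}
    for g, c in zip(df.iloc[:, 0], df.iloc[:, 1]):
        g, c = str(g).strip(), str(c).strip()
        if g in assignments and assignments[g] != c:
            raise DataValidationError(
                f"{path}: gene {g!r} labeled both {assignments[g]!r} and {c!r}"
            )
        assignments[g] = c
    return LabelMap(assignments)


def write_labels(labels: LabelMap, path: str | Path, delimiter: str | None = None) -> None:
    sep = _delimiter_for(path, delimiter)
    with open(path, "w") as fh:
        for g, c in labels.assignments.items():
            fh.write(f"{g}{sep}{c}\n")


def filter_low_fold_change(fm: FeatureMatrix, log2_threshold: float = 1.0) -> FeatureMatrix:
    """Drop genes whose fold change is below threshold under *all* contrasts.

    A gene is kept iff ``|log2 fold change| >= log2_threshold`` for at least one
    feature; the default 1.0 removes genes with fold change < 2 everywhere.
    """
    if log2_threshold < 0:
        raise ValueError("log2_threshold must be >= 0")
    keep = np.max(np.abs(fm.values), axis=1) >= log2_threshold
    return FeatureMatrix(
        [g for g, k in zip(fm.gene_ids, keep) if k],
        list(fm.feature_ids),
        fm.values[keep],
    )


def subset_columns(fm: FeatureMatrix, feature_ids: Sequence[str]) -> FeatureMatrix:
    """Return the matrix restricted to ``feature_ids``, in the requested order."""
    pos = {f: j for j, f in enumerate(fm.feature_ids)}
    cols = []
    for f in feature_ids:
        if f not in pos:
            raise KeyError(f"unknown feature id: {f!r}")
        cols.append(pos[f])
    return FeatureMatrix(list(fm.gene_ids), list(feature_ids), fm.values[:, cols])


def align(fm: FeatureMatrix, labels: LabelMap) -> tuple[FeatureMatrix, LabelMap]:
    """Intersect matrix rows with labeled genes (matrix row order preserved).

    Genes present in the matrix but unlabeled are dropped with a logged count;
    labels without a matrix row are dropped likewise.
    """
    labeled = set(labels.assignments)
    keep = [g in labeled for g in fm.gene_ids]
    n_dropped = fm.n_genes - sum(keep)
    if n_dropped:
        logger.info("align: dropped %d unlabeled genes from the feature matrix", n_dropped)
    kept_genes = [g for g, k in zip(fm.gene_ids, keep) if k]
    n_orphan = len(labeled) - len(kept_genes)
    if n_orphan:
        logger.info("align: %d labeled genes have no matrix row and are ignored", n_orphan)
    out_fm = FeatureMatrix(kept_genes, list(fm.feature_ids), fm.values[np.array(keep, bool)])
    return out_fm, labels.subset(kept_genes)


def ranking_table(scores: Sequence) -> pd.DataFrame:
    """Tabulate scan results: subset, per-run GSI, mean GSI, rank, tie flag."""
    rows = []
    for s in scores:
        row: dict[str, object] = {"subset": "+".join(s.features)}
        if s.failed:
            row.update({"mean_gsi": np.nan, "rank": None, "tied": False, "failed": True})
        else:
            for r, g in enumerate(s.run_gsi, start=1):
                row[f"gsi_run{r}"] = g
            row.update({"mean_gsi": s.mean_gsi, "rank": s.rank, "tied": s.tied, "failed": False})
        rows.append(row)
    df = pd.DataFrame(rows)
    if "rank" in df and df["rank"].notna().any():
        df = df.sort_values(["rank", "subset"], na_position="last").reset_index(drop=True)
    return df


def write_ranking_table(scores: Sequence, path: str | Path, delimiter: str | None = None) -> None:
    sep = _delimiter_for(path, delimiter)
    ranking_table(scores).to_csv(path, sep=sep, index=False, float_format="%.6g")
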