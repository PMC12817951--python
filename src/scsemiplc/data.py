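"""Core containers: expression matrices and labeled/unlabeled splits.

Cells are rows, genes are columns. Class labels are stored 0-based and
contiguous internally; the 1-based convention of label files applies only
at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ExpressionMatrix", "LabeledSet", "UnlabeledSet", "encode_labels"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")


@dataclass
class ExpressionMatrix:
    """A cells x genes numeric matrix with cell and gene identifiers."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional (cells x genes)")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError(
                f"row count {self.values.shape[0]} != number of cell ids "
                f"{len(self.cell_ids)}"
            )
        if self.values.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"column count {self.values.shape[1]} != number of gene ids "
                f"{len(self.gene_ids)}"
            )
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[index],
            [self.cell_ids[i] for i in index],
            list(self.gene_ids),
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index)
        return ExpressionMatrix(
            self.values[:, index],
            list(self.cell_ids),
            [self.gene_ids[i] for i in index],
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.cell_ids), list(self.gene_ids)
        )


def encode_labels(
    labels: Sequence, class_names: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Map arbitrary label values to 0-based contiguous integer codes.

    Class order is sorted order of the distinct string representations
    unless an explicit ``class_names`` order is given.
    """
    labels = [str(v) for v in labels]
    if class_names is None:
        class_names = sorted(set(labels))
    else:
        class_names = [str(c) for c in class_names]
        unknown = set(labels) - set(class_names)
        if unknown:
            raise ValueError(f"labels not in class_names: {sorted(unknown)}")
    lut = {name: i for i, name in enumerate(class_names)}
    return np.array([lut[v] for v in labels], dtype=np.int64), list(class_names)


@dataclass
class LabeledSet:
    """The labeled portion S = {(X, Y)} of a semi-supervised problem."""

    matrix: ExpressionMatrix
    labels: np.ndarray  # 0-based codes, aligned to matrix rows
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or len(self.labels) != self.matrix.n_cells:
            raise ValueError("label vector must align with matrix rows")
        if not self.class_names:
            self.class_names = [str(i + 1) for i in range(int(self.labels.max()) + 1)]
        c = len(self.class_names)
        if self.labels.min() < 0 or self.labels.max() >= c:
            raise ValueError(f"labels must lie in [0, {c})")
        present = np.bincount(self.labels, minlength=c)
        if np.any(present == 0):
            missing = [self.class_names[i] for i in np.flatnonzero(present == 0)]
            raise ValueError(f"classes with no labeled cells: {missing}")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class UnlabeledSet:
    """The unlabeled portion T = {X}; genes must match the paired LabeledSet."""

    matrix: ExpressionMatrix

    def validate_against(self, labeled: LabeledSet) -> None:
        if self.matrix.gene_ids != labeled.matrix.gene_ids:
            raise ValueError("unlabeled gene ids differ from labeled gene ids")
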