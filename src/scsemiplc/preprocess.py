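"""Filtering, normalization, HVG selection, scaling and labeled/unlabeled splits.

The pipeline order is fixed: filter -> library-size normalize (+log1p) ->
highly-variable-gene selection -> zero-mean/unit-variance scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import ExpressionMatrix, LabeledSet, UnlabeledSet, encode_labels

__all__ = [
    "PreprocessConfig",
    "EmptyResultError",
    "filter_cells_and_genes",
    "normalize_and_log",
    "select_hvg",
    "scale_unit_variance",
    "split_by_label_fraction",
    "run_pipeline",
]


class EmptyResultError(ValueError):
    """Raised when a filtering step removes every cell or every gene."""


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing pipeline.

    ``min_genes_per_cell`` / ``min_cells_per_gene`` implement the
    "fewer than N expressed" exclusion rules; "expressed" means a strictly
    positive raw value.
    """

    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    n_hvg: int = 2000
    normalize_target: float = 1e4
    log_transform: bool = True
    hvg_on_normalized: bool = True

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 1 or self.min_cells_per_gene < 1:
            raise ValueError("filtering thresholds must be positive")
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be positive")
        if self.normalize_target <= 0:
            raise ValueError("normalize_target must be positive")


def filter_cells_and_genes(
    m: ExpressionMatrix, cfg: PreprocessConfig
) -> ExpressionMatrix:
    """Drop low-coverage cells and rarely expressed genes in one pass.

    Both counts are taken on the ORIGINAL matrix: a cell survives if it
    expresses at least ``min_genes_per_cell`` genes, a gene survives if it
    is expressed in at least ``min_cells_per_gene`` cells, evaluated
    jointly rather than sequentially.
    """
    expressed = m.values > 0
    genes_per_cell = expressed.sum(axis=1)
    cells_per_gene = expressed.sum(axis=0)
    keep_cells = np.flatnonzero(genes_per_cell >= cfg.min_genes_per_cell)
    keep_genes = np.flatnonzero(cells_per_gene >= cfg.min_cells_per_gene)
    if keep_cells.size == 0:
        raise EmptyResultError(
            f"all {m.n_cells} cells have fewer than "
            f"{cfg.min_genes_per_cell} expressed genes"
        )
    if keep_genes.size == 0:
        raise EmptyResultError(
            f"all {m.n_genes} genes are expressed in fewer than "
            f"{cfg.min_cells_per_gene} cells"
        )
    return m.subset_cells(keep_cells).subset_genes(keep_genes)


def normalize_and_log(m: ExpressionMatrix, cfg: PreprocessConfig) -> ExpressionMatrix:
    """Scale each cell to a fixed total, then optionally log1p-transform."""
    if np.any(m.values < 0):
        raise ValueError("normalization expects non-negative values")
    totals = m.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"{zero.size} cell(s) with zero total counts "
            f"(e.g. {m.cell_ids[zero[0]]!r}); filter cells first"
        )
    out = m.values * (cfg.normalize_target / totals)[:, None]
    if cfg.log_transform:
        out = np.log1p(out)
    return ExpressionMatrix(out, list(m.cell_ids), list(m.gene_ids))


def select_hvg(m: ExpressionMatrix, n_hvg: int) -> ExpressionMatrix:
    """Keep the ``n_hvg`` genes with largest per-gene standard deviation.

    Ties are broken toward the earlier gene; surviving genes keep their
    original relative order.
    """
    if n_hvg > m.n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds gene count {m.n_genes}")
    sd = m.values.std(axis=0, ddof=0)
    order = np.argsort(-sd, kind="stable")  # stable: ties resolve to lower index
    keep = np.sort(order[:n_hvg])
    return m.subset_genes(keep)


def scale_unit_variance(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene to mean 0 and scale to unit (population) variance.

    Constant genes become all-zero columns rather than NaN.
    """
    if m.n_cells < 2:
        raise ValueError("scaling requires at least 2 cells")
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    out = (m.values - mean) / safe
    out[:, sd == 0] = 0.0
    return ExpressionMatrix(out, list(m.cell_ids), list(m.gene_ids))


def run_pipeline(
    m: ExpressionMatrix, cfg: PreprocessConfig
) -> tuple[ExpressionMatrix, np.ndarray]:
    """filter -> normalize(+log) -> HVG -> scale.

    Returns the processed matrix and the integer indices of the cells
    retained from the input (so sidecar label vectors can be subset).
    """
    filtered = filter_cells_and_genes(m, cfg)
    id_index = {c: i for i, c in enumerate(m.cell_ids)}
    kept = np.array([id_index[c] for c in filtered.cell_ids], dtype=np.int64)
    norm = normalize_and_log(filtered, cfg)
    n_hvg = min(cfg.n_hvg, norm.n_genes)
    hvg_input = norm if cfg.hvg_on_normalized else filtered
    hvg = select_hvg(hvg_input, n_hvg)
    if not cfg.hvg_on_normalized:
        gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
        hvg = norm.subset_genes(np.array([gene_pos[g] for g in hvg.gene_ids]))
    return scale_unit_variance(hvg), kept


def split_by_label_fraction(
    m: ExpressionMatrix,
    labels: Sequence,
    p: float,
    seed: int,
    class_names: Sequence[str] | None = None,
) -> tuple[LabeledSet, UnlabeledSet, np.ndarray]:
    """Stratified labeled/unlabeled split with labeled fraction ``p``.

    Per class, round(p * class_size) cells (half-up, floor of 1) are drawn
    into the labeled set; the complement forms the unlabeled set. Returns
    ``(labeled, unlabeled, held_out_truth)`` where ``held_out_truth`` holds
    the 0-based true codes of the unlabeled cells, for evaluation only.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    codes, names = encode_labels(labels, class_names)
    if len(codes) != m.n_cells:
        raise ValueError("label vector must align with matrix rows")
    c = len(names)
    if p * m.n_cells < c:
        raise ValueError(
            f"p={p} yields fewer labeled cells than the {c} classes"
        )
    counts = np.bincount(codes, minlength=c)
    if np.any(counts == 0):
        raise ValueError("every class must have at least one cell")
    rng = np.random.default_rng(seed)
    labeled_idx: list[np.ndarray] = []
    for cls in range(c):
        members = np.flatnonzero(codes == cls)
        n_lab = max(1, int(np.floor(p * members.size + 0.5)))
        n_lab = min(n_lab, members.size)
        labeled_idx.append(rng.choice(members, size=n_lab, replace=False))
    lab = np.sort(np.concatenate(labeled_idx))
    mask = np.zeros(m.n_cells, dtype=bool)
    mask[lab] = True
    unlab = np.flatnonzero(~mask)
    labeled = LabeledSet(m.subset_cells(lab), codes[lab], list(names))
    unlabeled = UnlabeledSet(m.subset_cells(unlab))
    return labeled, unlabeled, codes[unlab]
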