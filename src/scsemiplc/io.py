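"""Readers and writers for expression matrices and label tables.

Supported formats: dense CSV/TSV (cells in rows, header row of gene ids,
first column cell ids), MatrixMarket MTX with barcodes.tsv / genes.tsv
sidecars (10X convention: stored genes x cells, transposed on load) and,
when anndata is importable, h5ad containers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import ExpressionMatrix

__all__ = [
    "read_dense",
    "write_dense",
    "read_mtx",
    "write_mtx",
    "read_h5ad",
    "write_h5ad",
    "read_labels",
    "write_labels",
    "load_expression",
]


def read_dense(path) -> ExpressionMatrix:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=np.float64),
        [str(c) for c in df.index],
        [str(g) for g in df.columns],
    )


def write_dense(m: ExpressionMatrix, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids).to_csv(path, sep=sep)


def _sidecar(path: Path, names: Sequence[str]) -> Path:
    for name in names:
        candidate = path.with_name(name)
        if candidate.exists():
            return candidate
    raise FileNotFoundError(
        f"no sidecar {names} next to {path}"
    )


def read_mtx(matrix_path, barcodes_path=None, genes_path=None) -> ExpressionMatrix:
    """10X-convention MTX: file stores genes x cells; returned cells x genes."""
    matrix_path = Path(matrix_path)
    if barcodes_path is None:
        barcodes_path = _sidecar(matrix_path, ["barcodes.tsv"])
    if genes_path is None:
        genes_path = _sidecar(matrix_path, ["genes.tsv", "features.tsv"])
    mat = scipy.io.mmread(matrix_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.float64).T  # genes x cells -> cells x genes
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    return ExpressionMatrix(mat, barcodes, genes)


def write_mtx(m: ExpressionMatrix, matrix_path) -> None:
    matrix_path = Path(matrix_path)
    matrix_path.parent.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csr_matrix(m.values.T)  # store genes x cells
    scipy.io.mmwrite(str(matrix_path), sparse)
    pd.Series(m.cell_ids).to_csv(
        matrix_path.with_name("barcodes.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(m.gene_ids).to_csv(
        matrix_path.with_name("genes.tsv"), sep="\t", header=False, index=False
    )


def read_h5ad(path) -> ExpressionMatrix:
    import anndata  # optional dependency

    adata = anndata.read_h5ad(path)
    x = adata.X
    if scipy.sparse.issparse(x):
        x = x.toarray()
    return ExpressionMatrix(
        np.asarray(x, dtype=np.float64),
        [str(c) for c in adata.obs_names],
        [str(g) for g in adata.var_names],
    )


def write_h5ad(m: ExpressionMatrix, path) -> None:
    import anndata

    adata = anndata.AnnData(X=m.values.copy())
    adata.obs_names = m.cell_ids
    adata.var_names = m.gene_ids
    adata.write_h5ad(path)


def read_labels(path) -> dict[str, str]:
    """Two-column TSV mapping cell_id -> cell_type (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("label file needs two columns: cell_id, cell_type")
    first = df.iloc[0]
    if str(first[0]).lower() in {"cell_id", "cell", "barcode"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(mapping: dict[str, str], path) -> None:
    pd.DataFrame(list(mapping.items())).to_csv(
        path, sep="\t", header=False, index=False
    )


def load_expression(path, **kwargs) -> ExpressionMatrix:
    """Dispatch on suffix: .mtx -> 10X triplet, .h5ad -> anndata,
    anything else -> dense CSV/TSV."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return read_mtx(path, **kwargs)
    if suffix == ".h5ad":
        return read_h5ad(path)
    return read_dense(path)
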