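"""Quality control and normalization for raw count matrices.

The pipeline is the standard scRNA-seq recipe: drop low-complexity cells,
drop rarely detected genes, scale every cell to a common total count, then
log1p. State transitions are enforced — the filters and normalization
require raw counts, and the log transform marks the matrix normalized so
the pipeline cannot be applied twice.
"""

from __future__ import annotations

import numpy as np

from .io_formats import ExpressionMatrix, NORMALIZED_LOG, RAW_COUNTS

__all__ = ["filter_cells", "filter_genes", "normalize_total",
           "log_transform", "preprocess", "select_highly_variable"]


def _require_raw(matrix: ExpressionMatrix, op: str) -> None:
    if matrix.state != RAW_COUNTS:
        raise ValueError(f"{op} requires raw counts; matrix state is "
                         f"{matrix.state!r}")


def filter_cells(matrix: ExpressionMatrix, min_genes: int = 200) -> ExpressionMatrix:
    """Keep cells detecting at least ``min_genes`` genes (value > 0).

    A cell with strictly fewer detected genes is removed; the boundary cell
    with exactly ``min_genes`` is retained. Order is preserved.
    """
    _require_raw(matrix, "filter_cells")
    detected = (matrix.values > 0).sum(axis=1)
    keep = detected >= min_genes
    if not keep.any():
        raise ValueError(
            f"filter_cells removed every cell at min_genes={min_genes}; "
            "lower the threshold")
    return matrix.subset_cells(keep)


def filter_genes(matrix: ExpressionMatrix,
                 min_cell_fraction: float = 0.001) -> ExpressionMatrix:
    """Keep genes detected in at least ``min_cell_fraction`` of cells.

    The comparison is real-valued: a gene passes iff
    ``n_detecting_cells >= min_cell_fraction * n_cells`` with the current
    (post cell-filter) cell count — no rounding of the required count.
    """
    _require_raw(matrix, "filter_genes")
    detecting = (matrix.values > 0).sum(axis=0)
    keep = detecting >= min_cell_fraction * matrix.n_cells
    if not keep.any():
        raise ValueError(
            "filter_genes removed every gene at "
            f"min_cell_fraction={min_cell_fraction}")
    return matrix.subset_genes(keep)


def normalize_total(matrix: ExpressionMatrix,
                    target_sum: float = 10_000.0) -> ExpressionMatrix:
    """Scale each cell so its counts sum to ``target_sum``."""
    _require_raw(matrix, "normalize_total")
    totals = matrix.values.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.sum(totals <= 0))
        raise ValueError(
            f"{bad} cell(s) have zero total count; filter cells first")
    values = matrix.values * (target_sum / totals)[:, None]
    # leaves the raw_counts state: values are fractional from here on
    return ExpressionMatrix(values, list(matrix.gene_ids),
                            list(matrix.cell_ids),
                            None if matrix.cell_names is None
                            else list(matrix.cell_names),
                            state=NORMALIZED_LOG)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Natural-log transform with pseudocount 1: x -> log(1 + x)."""
    if np.any(matrix.values < 0):
        raise ValueError("log_transform requires non-negative values")
    out = ExpressionMatrix(np.log1p(matrix.values), list(matrix.gene_ids),
                           list(matrix.cell_ids),
                           None if matrix.cell_names is None
                           else list(matrix.cell_names),
                           state=NORMALIZED_LOG)
    return out


def preprocess(matrix: ExpressionMatrix, min_genes: int = 200,
               min_cell_fraction: float = 0.001,
               target_sum: float = 10_000.0,
               highly_variable: int | None = None) -> ExpressionMatrix:
    """Full pipeline: filter cells, filter genes, normalize, log1p.

    ``highly_variable`` optionally restricts to the top-N variable genes
    (delegated to scanpy) after the log transform.
    """
    matrix = filter_cells(matrix, min_genes=min_genes)
    matrix = filter_genes(matrix, min_cell_fraction=min_cell_fraction)
    matrix = normalize_total(matrix, target_sum=target_sum)
    matrix = log_transform(matrix)
    if highly_variable is not None:
        matrix = select_highly_variable(matrix, n_top=highly_variable)
    return matrix


def select_highly_variable(matrix: ExpressionMatrix,
                           n_top: int = 2000) -> ExpressionMatrix:
    """Restrict to the top ``n_top`` highly variable genes (scanpy)."""
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(X=matrix.values.copy())
    sc.pp.highly_variable_genes(adata, n_top_genes=min(n_top, matrix.n_genes),
                                flavor="seurat")
    return matrix.subset_genes(np.asarray(adata.var["highly_variable"]))
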