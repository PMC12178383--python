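"""Single-cell expression linkage: dot-plot statistics per cell type.

Given an annotated (already normalized, log-transformed) expression
matrix, summarize each gene of interest per cell type by:

* mean expression over the cells of the type;
* the gene-wise Z of those means across cell types (population-SD
  standardization; a gene whose means are constant gets Z = 0);
* the fraction of cells with expression strictly greater than 0.

These are the statistics behind the classic dot plot used to assign
candidate plasma biomarkers to candidate producer cell types.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CellTypeSummary:
    mean_expression: pd.DataFrame   # genes × cell types
    z_mean: pd.DataFrame
    pct_expressing: pd.DataFrame
    cell_counts: pd.Series
    z_sd_convention: str = "population"


def read_annotated_expression(matrix_path, annotation_path=None
                              ) -> tuple[pd.DataFrame, pd.Series]:
    """Read a genes × cells matrix plus a barcode → cell-type annotation.

    ``matrix_path`` may be a dense CSV (genes as rows, barcodes as
    columns) or a directory with MatrixMarket triplet files
    (matrix.mtx, genes.tsv, barcodes.tsv[, annotation.tsv]).  Cells
    without an annotation are dropped with a logged count; if more than
    half the barcodes have no annotation, the pairing is presumed wrong
    and an error is raised.
    """
    matrix_path = str(matrix_path)
    if os.path.isdir(matrix_path):
        from scipy.io import mmread

        mat = mmread(os.path.join(matrix_path, "matrix.mtx")).toarray()
        genes = pd.read_csv(os.path.join(matrix_path, "genes.tsv"),
                            header=None)[0].astype(str)
        barcodes = pd.read_csv(os.path.join(matrix_path, "barcodes.tsv"),
                               header=None)[0].astype(str)
        expr = pd.DataFrame(mat, index=genes.to_numpy(), columns=barcodes.to_numpy())
        if annotation_path is None:
            annotation_path = os.path.join(matrix_path, "annotation.tsv")
    else:
        expr = pd.read_csv(matrix_path, index_col=0)
        expr.index = expr.index.astype(str)
    if annotation_path is None:
        raise ValueError("an annotation file is required for dense CSV input")

    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    labels = ann.iloc[:, 0].astype(str)
    labels.index = labels.index.astype(str)

    known = expr.columns.intersection(labels.index)
    n_drop = expr.shape[1] - len(known)
    if len(known) < 0.5 * expr.shape[1]:
        raise ValueError(
            f"only {len(known)}/{expr.shape[1]} barcodes annotated; "
            "matrix and annotation files are probably mismatched"
        )
    if n_drop:
        logger.info("dropping %d unannotated cells", n_drop)
    expr = expr[known]
    return expr, labels.loc[known]


def celltype_dot_stats(expression: pd.DataFrame, labels: pd.Series,
                       genes: list[str] | None = None) -> CellTypeSummary:
    """Mean expression, gene-wise Z of means, and percent-expressing per
    cell type for the requested genes (all genes by default)."""
    labels = pd.Series(labels)
    labels = labels.reindex(expression.columns)
    if labels.isna().any():
        raise ValueError("every cell must carry a cell-type label")
    if genes is not None:
        missing = [g for g in genes if g not in expression.index]
        if missing:
            raise ValueError(f"genes not in matrix: {missing}")
        expression = expression.loc[genes]

    grouped = expression.T.groupby(labels)
    counts = grouped.size()
    if (counts < 1).any():
        raise ValueError("every cell type needs at least one cell")
    means = grouped.mean().T                     # genes × types
    pct = grouped.apply(lambda block: (block > 0).mean()).T

    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    z = means.sub(mu, axis=0).div(sd.where(sd > 0), axis=0).fillna(0.0)

    return CellTypeSummary(
        mean_expression=means, z_mean=z, pct_expressing=pct,
        cell_counts=counts, z_sd_convention="population",
    )


def rank_genes_by_celltype(summary: CellTypeSummary, cell_type: str) -> list[str]:
    """Genes ordered by descending mean expression in ``cell_type``;
    ties break alphabetically."""
    if cell_type not in summary.mean_expression.columns:
        raise ValueError(f"unknown cell type {cell_type!r}")
    col = summary.mean_expression[cell_type]
    order = sorted(col.index, key=lambda g: (-col[g], g))
    return list(order)


def join_umap_coordinates(expression: pd.DataFrame, coords: pd.DataFrame,
                          genes: list[str]) -> pd.DataFrame:
    """Plumbing: join per-cell expression of selected genes onto
    user-supplied 2-D embedding coordinates (index = barcode)."""
    common = coords.index.intersection(expression.columns)
    out = coords.loc[common, coords.columns[:2]].copy()
    for g in genes:
        out[g] = expression.loc[g, common].to_numpy()
    return out
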