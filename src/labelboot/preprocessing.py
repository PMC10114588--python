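"""Shared preprocessing: Pearson-residual HVG selection, log transform, L2 norm.

Every classifier sees the same representation: counts restricted to the top
highly variable genes (ranked by variance of analytic Pearson residuals under a
negative-binomial null), then ``log(x + pseudocount)`` and cell-wise L2
normalization.

A deliberate convention, inherited from the benchmarked workflow: the log is
taken of ``x + 0.001``, NOT ``log1p``. A zero count therefore maps to
``log(0.001) ≈ -6.9`` rather than 0, and an all-zero cell becomes a constant
negative vector (which normalizes fine). Cells with no counts at all on the
selected genes are additionally flagged in ``ProcessedMatrix.zero_cells`` so
classifiers can refuse to annotate them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .io_formats import ExpressionDataset

__all__ = [
    "ProcessedMatrix",
    "select_hvgs_pearson_residuals",
    "log_l2_normalize",
    "preprocess",
]

DEFAULT_N_HVGS = 1000
DEFAULT_PSEUDOCOUNT = 1e-3
DEFAULT_THETA = 100.0


@dataclass
class ProcessedMatrix:
    """HVG-restricted, log-transformed, per-cell L2-normalized expression."""

    values: np.ndarray          # cells x hvgs, dense float64, unit L2 rows
    cell_ids: np.ndarray
    hvg_ids: np.ndarray
    params: dict = field(default_factory=dict)
    zero_cells: np.ndarray = None  # bool mask: all-zero raw counts on the HVG set

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.zero_cells is None:
            self.zero_cells = np.zeros(self.values.shape[0], dtype=bool)
        if self.values.shape != (len(self.cell_ids), len(self.hvg_ids)):
            raise ValueError("values shape does not match ids")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def subset(self, rows: Sequence[int]) -> "ProcessedMatrix":
        idx = np.asarray(rows, dtype=int)
        return ProcessedMatrix(
            values=self.values[idx],
            cell_ids=np.asarray(self.cell_ids, dtype=object)[idx],
            hvg_ids=self.hvg_ids,
            params=self.params,
            zero_cells=self.zero_cells[idx],
        )


def pearson_residual_variance(
    dataset: ExpressionDataset, theta: float = DEFAULT_THETA, chunk: int = 512
) -> np.ndarray:
    """Per-gene variance of clipped analytic Pearson residuals.

    For cell c and gene g, with mu_cg = rowsum_c * colsum_g / grand_sum,
    r_cg = (x_cg - mu_cg) / sqrt(mu_cg + mu_cg^2 / theta), clipped to
    +/- sqrt(n_cells). Returns the population variance of r over cells, per
    gene. Computed in gene chunks so the dense residual matrix never
    materializes in full.
    """
    X = sp.csc_matrix(dataset.counts, dtype=np.float64)
    n_cells, n_genes = X.shape
    row_sums = np.asarray(X.sum(axis=1)).ravel()
    col_sums = np.asarray(X.sum(axis=0)).ravel()
    grand = row_sums.sum()
    if grand == 0:
        raise ValueError("count matrix is entirely zero")
    clip = np.sqrt(n_cells)
    out = np.empty(n_genes)
    for start in range(0, n_genes, chunk):
        stop = min(start + chunk, n_genes)
        dense = np.asarray(X[:, start:stop].todense())
        mu = np.outer(row_sums, col_sums[start:stop]) / grand
        denom = np.sqrt(mu + mu * mu / theta)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (dense - mu) / denom
        r[~np.isfinite(r)] = 0.0  # genes/cells with zero totals
        np.clip(r, -clip, clip, out=r)
        out[start:stop] = r.var(axis=0)
    return out


def select_hvgs_pearson_residuals(
    dataset: ExpressionDataset,
    n_hvgs: int = DEFAULT_N_HVGS,
    theta: float = DEFAULT_THETA,
) -> np.ndarray:
    """Top ``n_hvgs`` gene ids by descending Pearson-residual variance.

    Deterministic: ties are broken by ascending gene id. If the dataset has
    fewer than ``n_hvgs`` genes, all genes are returned (still ranked).
    """
    if n_hvgs < 1:
        raise ValueError("n_hvgs must be >= 1")
    var = pearson_residual_variance(dataset, theta=theta)
    gene_ids = np.asarray(dataset.gene_ids, dtype=object)
    order = sorted(range(len(gene_ids)), key=lambda i: (-var[i], str(gene_ids[i])))
    k = min(n_hvgs, len(gene_ids))
    return gene_ids[np.asarray(order[:k], dtype=int)]


def log_l2_normalize(
    dataset: ExpressionDataset,
    hvg_ids: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ProcessedMatrix:
    """``log(counts[:, hvg_ids] + pseudocount)`` then row-wise L2 normalization.

    The input dataset is not modified. All-zero-count rows (on the HVG set) are
    flagged in ``zero_cells``; they still normalize (the log of the pseudocount
    is a nonzero constant).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    sub = dataset.subset_genes(hvg_ids)
    dense = np.asarray(sub.counts.todense(), dtype=np.float64)
    zero_cells = ~np.any(dense > 0, axis=1)
    vals = np.log(dense + pseudocount)
    norms = np.linalg.norm(vals, axis=1)
    nonzero = norms > 0
    vals[nonzero] /= norms[nonzero, None]
    return ProcessedMatrix(
        values=vals,
        cell_ids=dataset.cell_ids,
        hvg_ids=np.asarray(list(hvg_ids), dtype=object),
        params={
            "n_hvgs": len(list(hvg_ids)),
            "pseudocount": float(pseudocount),
        },
        zero_cells=zero_cells,
    )


def preprocess(
    dataset: ExpressionDataset,
    n_hvgs: int = DEFAULT_N_HVGS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    theta: float = DEFAULT_THETA,
    hvg_ids: Optional[Sequence[str]] = None,
) -> ProcessedMatrix:
    """HVG selection (unless ``hvg_ids`` given) followed by log + L2 transform.

    Passing ``hvg_ids`` applies a previously selected gene set — the standard
    route for processing a query with the reference's HVGs.
    """
    if hvg_ids is None:
        hvg_ids = select_hvgs_pearson_residuals(dataset, n_hvgs, theta=theta)
    pm = log_l2_normalize(dataset, hvg_ids, pseudocount)
    pm.params["theta"] = float(theta)
    return pm
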