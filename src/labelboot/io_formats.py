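"""On-disk formats and the in-memory dataset contract.

Count matrices travel as Matrix Market (.mtx) coordinate files plus one-id-per-line
gene/cell files (10x convention: genes x cells on disk, cells x genes in memory).
Labels and predictions are plain CSV tables keyed by ``cell_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "ExpressionDataset",
    "LabelPrediction",
    "UNASSIGNED",
    "read_mtx_dataset",
    "write_mtx_dataset",
    "read_label_table",
    "write_predictions_csv",
    "read_predictions_csv",
    "concatenate_datasets",
]

#: Sentinel label for cells a classifier declines to annotate.
UNASSIGNED = "UNASSIGNED"


@dataclass
class LabelPrediction:
    """A single query-cell annotation.

    ``label`` is drawn from the reference label set or is the :data:`UNASSIGNED`
    sentinel; ``confidence``, when present, lies in [0, 1].
    """

    cell_id: str
    label: str
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.confidence is not None:
            c = float(self.confidence)
            if not (0.0 <= c <= 1.0) or not np.isfinite(c):
                raise ValueError(
                    f"confidence must lie in [0, 1], got {self.confidence!r}"
                )
            self.confidence = c


@dataclass
class ExpressionDataset:
    """Raw counts, cells x genes, with ids and optional labels/batch tags.

    ``counts`` is kept sparse (CSR); all downstream operations accept sparse
    input. Labels and batch tags are per-cell string arrays aligned with
    ``cell_ids``.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    labels: Optional[np.ndarray] = None
    batch: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_cells, n_genes = self.counts.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cell ids x {len(self.gene_ids)} gene ids"
            )
        if self.counts.nnz:
            data = self.counts.data
            if not np.all(np.isfinite(data)):
                raise ValueError("counts contain non-finite entries")
            if data.min() < 0:
                raise ValueError("counts contain negative entries")
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")
        for name, arr in (("labels", self.labels), ("batch", self.batch)):
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=object)
            if len(arr) != n_cells:
                raise ValueError(f"{name} length {len(arr)} != {n_cells} cells")
            if any(not isinstance(x, str) or not x for x in arr):
                raise ValueError(f"{name} must be non-empty strings")
            setattr(self, name, arr)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def label_counts(self) -> dict[str, int]:
        """Per-cell-type abundances, sorted by label."""
        if self.labels is None:
            raise ValueError("dataset has no labels")
        uniq, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    def subset_cells(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            counts=self.counts[idx],
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            labels=None if self.labels is None else self.labels[idx],
            batch=None if self.batch is None else self.batch[idx],
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            cols = np.array([pos[g] for g in gene_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown gene id {e.args[0]!r}") from None
        return ExpressionDataset(
            counts=self.counts[:, cols],
            cell_ids=self.cell_ids,
            gene_ids=np.asarray(list(gene_ids), dtype=object),
            labels=self.labels,
            batch=self.batch,
        )


def _read_ids(path: Path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    ids = [ln for ln in lines if ln]
    # tolerate 10x-style two/three-column gene files: use the first column
    return np.asarray([ln.split("\t")[0] for ln in ids], dtype=object)


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read a cell_id,label[,batch] CSV; validates header and duplicates."""
    df = pd.read_csv(path, dtype=str)
    required = {"cell_id", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValueError(f"duplicate cell_id rows in label table: {dups[:5]}")
    return df


def read_mtx_dataset(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    labels_path: str | Path | None = None,
    orientation: str = "genes-by-cells",
) -> ExpressionDataset:
    """Read a Matrix Market count matrix with id files into a validated dataset.

    Parameters
    ----------
    orientation
        ``"genes-by-cells"`` (10x convention, default) transposes the stored
        matrix to cells x genes; ``"cells-by-genes"`` takes it as stored.
    labels_path
        Optional CSV with header ``cell_id,label[,batch]``. Rows are matched to
        cells by id, not by order, and must cover every cell.
    """
    if orientation not in ("genes-by-cells", "cells-by-genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    mat = sp.coo_matrix(mmread(str(matrix_path)))
    if mat.nnz and mat.data.min() < 0:
        raise ValueError("matrix contains negative count entries")
    if orientation == "genes-by-cells":
        mat = mat.T
    genes = _read_ids(Path(genes_path))
    cells = _read_ids(Path(cells_path))
    if mat.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {mat.shape} (as cells x genes, orientation="
            f"{orientation!r}) does not match {len(cells)} cells x "
            f"{len(genes)} genes"
        )
    labels = batch = None
    if labels_path is not None:
        table = read_label_table(labels_path)
        unknown = set(table["cell_id"]) - set(cells)
        if unknown:
            raise ValueError(
                f"label table cell_ids not present in cells file: "
                f"{sorted(unknown)[:5]}"
            )
        by_id = table.set_index("cell_id")
        missing = [c for c in cells if c not in by_id.index]
        if missing:
            raise ValueError(f"cells missing from label table: {missing[:5]}")
        labels = by_id.loc[cells, "label"].to_numpy(dtype=object)
        if "batch" in table.columns and by_id["batch"].notna().all():
            batch = by_id.loc[cells, "batch"].to_numpy(dtype=object)
    return ExpressionDataset(
        counts=mat.tocsr(), cell_ids=cells, gene_ids=genes,
        labels=labels, batch=batch,
    )


def write_mtx_dataset(dataset: ExpressionDataset, outdir: str | Path,
                      prefix: str = "") -> dict[str, Path]:
    """Write matrix.mtx (genes x cells) + genes.txt + cells.txt [+ labels.csv]."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}matrix.mtx",
        "genes": outdir / f"{prefix}genes.txt",
        "cells": outdir / f"{prefix}cells.txt",
    }
    mmwrite(str(paths["matrix"]), sp.coo_matrix(dataset.counts.T))
    paths["genes"].write_text("\n".join(map(str, dataset.gene_ids)) + "\n")
    paths["cells"].write_text("\n".join(map(str, dataset.cell_ids)) + "\n")
    if dataset.labels is not None:
        table = pd.DataFrame(
            {"cell_id": dataset.cell_ids, "label": dataset.labels}
        )
        if dataset.batch is not None:
            table["batch"] = dataset.batch
        paths["labels"] = outdir / f"{prefix}labels.csv"
        table.to_csv(paths["labels"], index=False)
    return paths


def write_predictions_csv(
    predictions: Sequence[LabelPrediction], path: str | Path
) -> None:
    """Write predictions as ``cell_id,predicted_label,confidence`` CSV.

    Missing confidences become empty fields; an empty prediction set yields a
    header-only file. Round-trips losslessly through
    :func:`read_predictions_csv`.
    """
    rows = [
        {
            "cell_id": p.cell_id,
            "predicted_label": p.label,
            "confidence": "" if p.confidence is None else repr(p.confidence),
        }
        for p in predictions
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "predicted_label", "confidence"])
    df.to_csv(path, index=False)


def read_predictions_csv(path: str | Path) -> list[LabelPrediction]:
    df = pd.read_csv(
        path, dtype={"cell_id": str, "predicted_label": str, "confidence": float}
    )
    out = []
    for row in df.itertuples(index=False):
        conf = None if pd.isna(row.confidence) else float(row.confidence)
        out.append(LabelPrediction(str(row.cell_id), str(row.predicted_label), conf))
    return out


def concatenate_datasets(
    datasets: Sequence[ExpressionDataset], batch_names: Sequence[str]
) -> ExpressionDataset:
    """Row-stack datasets sharing an identical gene list, tagging by batch.

    No batch correction or rescaling of any kind is applied: counts pass
    through numerically unchanged. Cell ids are disambiguated by
    ``"{batch}:{cell_id}"`` prefixing.
    """
    if len(datasets) != len(batch_names):
        raise ValueError("need one batch name per dataset")
    if not datasets:
        raise ValueError("no datasets given")
    ref_genes = datasets[0].gene_ids
    for d in datasets[1:]:
        if len(d.gene_ids) != len(ref_genes) or not np.array_equal(
            d.gene_ids, ref_genes
        ):
            raise ValueError("gene id lists differ between datasets")
    counts = sp.vstack([d.counts for d in datasets], format="csr")
    cell_ids = np.concatenate(
        [
            np.asarray([f"{b}:{c}" for c in d.cell_ids], dtype=object)
            for d, b in zip(datasets, batch_names)
        ]
    )
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("duplicate cell ids after batch prefixing")
    batch = np.concatenate(
        [np.full(d.n_cells, b, dtype=object) for d, b in zip(datasets, batch_names)]
    )
    labels = None
    if all(d.labels is not None for d in datasets):
        labels = np.concatenate([d.labels for d in datasets])
    return ExpressionDataset(
        counts=counts, cell_ids=cell_ids, gene_ids=ref_genes,
        labels=labels, batch=batch,
    )
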