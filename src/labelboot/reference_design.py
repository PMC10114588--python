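"""Reference variants: capped subsamples, permutation replicates, subset series
for bootstrapping, and mosaic multi-source references.

The central design knob is the *cap*: the maximum number of cells any one cell
type may contribute to a subsampled reference. Types rarer than the cap are
included in full, so a capped reference may remain unbalanced. The default cap
sweep {38, 100, 250, 500, 1000, 1500, 2000, 3000} with 20 permutations per cap
matches the benchmarked design.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .classifiers import ClassifierLike, predict
from .io_formats import ExpressionDataset, concatenate_datasets
from .preprocessing import (
    DEFAULT_N_HVGS,
    ProcessedMatrix,
    preprocess,
    select_hvgs_pearson_residuals,
)

__all__ = [
    "DEFAULT_CAPS",
    "DEFAULT_N_PERM",
    "ReferenceSubset",
    "SubsetSeries",
    "subsample_reference",
    "build_subset_series",
    "assemble_mosaic",
    "abundance_report",
    "sweep_caps",
]

DEFAULT_CAPS = (38, 100, 250, 500, 1000, 1500, 2000, 3000)
DEFAULT_N_PERM = 20


@dataclass
class ReferenceSubset:
    """An index set into a parent dataset, with its per-type cap and seed."""

    cell_indices: np.ndarray
    cap: int
    seed: int
    parent_id: str = ""

    def __post_init__(self) -> None:
        self.cell_indices = np.asarray(self.cell_indices, dtype=int)
        if len(set(self.cell_indices.tolist())) != len(self.cell_indices):
            raise ValueError("duplicate cell indices in subset")


@dataclass
class SubsetSeries:
    """One capped subset per distinct cell type; subset j's cap is type j's
    abundance in the parent reference."""

    subsets: list[ReferenceSubset]
    type_order: list[str]  # type whose abundance set each subset's cap


def _type_stream(seed: int, type_name: str) -> np.random.Generator:
    # independent substream per (seed, type): adding a type never reshuffles
    # another type's sample
    digest = hashlib.blake2s(
        type_name.encode("utf-8"), digest_size=4
    ).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int.from_bytes(digest, "little")])
    )


def subsample_reference(
    dataset: ExpressionDataset, cap: int, seed: int, parent_id: str = ""
) -> ReferenceSubset:
    """Uniform within-type sampling without replacement, capped at ``cap``.

    Types with at most ``cap`` cells are included in full; the result may
    therefore still be unbalanced. Deterministic in (dataset, cap, seed).
    """
    if dataset.labels is None:
        raise ValueError("dataset must be labeled to subsample per type")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    labels = dataset.labels.astype(str)
    chosen = []
    for t in sorted(set(labels)):
        idx = np.nonzero(labels == t)[0]
        if len(idx) > cap:
            rng = _type_stream(seed, t)
            idx = idx[rng.choice(len(idx), size=cap, replace=False)]
        chosen.append(np.sort(idx))
    return ReferenceSubset(
        cell_indices=np.sort(np.concatenate(chosen)),
        cap=int(cap),
        seed=int(seed),
        parent_id=parent_id,
    )


def build_subset_series(dataset: ExpressionDataset, seed: int) -> SubsetSeries:
    """One subset per cell type, capped at that type's own abundance.

    The subset whose cap is the largest abundance equals the full dataset; the
    subset capped at the rarest type's abundance is (near-)balanced.
    """
    if dataset.labels is None:
        raise ValueError("dataset must be labeled")
    abundances = dataset.label_counts()
    if len(abundances) < 2:
        raise ValueError("subset series needs at least 2 cell types")
    subsets, order = [], []
    for j, t in enumerate(sorted(abundances)):
        subsets.append(
            subsample_reference(
                dataset, cap=abundances[t], seed=seed * 1000 + j,
                parent_id=f"type={t}",
            )
        )
        order.append(t)
    return SubsetSeries(subsets=subsets, type_order=order)


def assemble_mosaic(
    datasets: Sequence[ExpressionDataset],
    batch_names: Sequence[str],
    gene_policy: str = "intersection",
) -> ExpressionDataset:
    """Concatenate labeled sources into one mosaic reference, uncorrected.

    The gene universe is the intersection of the sources' gene lists (in the
    first source's order); ``gene_policy="union"`` instead unions them,
    zero-filling genes a source never measured. Counts pass through
    bit-identically; per-type abundances add across sources.
    """
    if gene_policy not in ("intersection", "union"):
        raise ValueError(f"unknown gene_policy {gene_policy!r}")
    if not datasets:
        raise ValueError("no datasets given")
    for d in datasets:
        if d.labels is None:
            raise ValueError("every mosaic source must be labeled")
    if gene_policy == "intersection":
        shared = set(datasets[0].gene_ids)
        for d in datasets[1:]:
            shared &= set(d.gene_ids)
        if not shared:
            raise ValueError("empty gene intersection across sources")
        genes = [g for g in datasets[0].gene_ids if g in shared]
        aligned = [d.subset_genes(genes) for d in datasets]
    else:
        genes = list(datasets[0].gene_ids)
        seen = set(genes)
        for d in datasets[1:]:
            for g in d.gene_ids:
                if g not in seen:
                    seen.add(g)
                    genes.append(g)
        aligned = []
        for d in datasets:
            import scipy.sparse as sp

            pos = {g: i for i, g in enumerate(d.gene_ids)}
            cols = [pos.get(g) for g in genes]
            mat = sp.lil_matrix((d.n_cells, len(genes)), dtype=d.counts.dtype)
            for j, c in enumerate(cols):
                if c is not None:
                    mat[:, j] = d.counts[:, c]
            aligned.append(
                ExpressionDataset(
                    counts=mat.tocsr(), cell_ids=d.cell_ids,
                    gene_ids=np.asarray(genes, dtype=object),
                    labels=d.labels, batch=d.batch,
                )
            )
    return concatenate_datasets(aligned, batch_names)


def abundance_report(dataset: ExpressionDataset) -> pd.DataFrame:
    """Tidy per-(cell type, batch) abundance table with per-type totals."""
    if dataset.labels is None:
        raise ValueError("dataset must be labeled")
    df = pd.DataFrame(
        {
            "cell_type": dataset.labels.astype(str),
            "batch": (
                dataset.batch.astype(str)
                if dataset.batch is not None
                else np.full(dataset.n_cells, "all")
            ),
        }
    )
    table = (
        df.value_counts(["cell_type", "batch"])
        .rename("n_cells")
        .reset_index()
        .sort_values(["cell_type", "batch"])
        .reset_index(drop=True)
    )
    totals = table.groupby("cell_type")["n_cells"].transform("sum")
    table["n_cells_total"] = totals
    return table


def sweep_caps(
    dataset: ExpressionDataset,
    query: ExpressionDataset,
    classifier: ClassifierLike,
    caps: Sequence[int] = DEFAULT_CAPS,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    n_hvgs: int = DEFAULT_N_HVGS,
    processed: Optional[tuple[ProcessedMatrix, ProcessedMatrix]] = None,
) -> pd.DataFrame:
    """Per-(cap, permutation, cell type) metric table for cap-sweep curves.

    For every cap and permutation: subsample the labeled reference, classify
    the query, and score per cell type. HVGs are selected once on the full
    reference so rows are comparable across caps. Returns a tidy frame with
    columns cap, perm, cell_type, accuracy, precision, f1, support.
    """
    if not caps:
        raise ValueError("caps must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if query.labels is None:
        raise ValueError("query must carry ground-truth labels")
    if processed is None:
        hvgs = select_hvgs_pearson_residuals(dataset, n_hvgs)
        ref_pm = preprocess(dataset, hvg_ids=hvgs)
        qry_pm = preprocess(query, hvg_ids=hvgs)
    else:
        ref_pm, qry_pm = processed
    truth = dict(zip(query.cell_ids.astype(str), query.labels.astype(str)))
    rows = []
    for cap in caps:
        for perm in range(n_perm):
            sub_seed = seed * 100_003 + cap * 101 + perm
            subset = subsample_reference(dataset, cap=cap, seed=sub_seed)
            preds = predict(
                classifier,
                ref_pm.subset(subset.cell_indices),
                dataset.labels[subset.cell_indices],
                qry_pm,
                seed=sub_seed % (2**31),
            )
            report = evaluation.evaluate(preds, truth)
            for _, r in report.per_class.iterrows():
                rows.append(
                    {
                        "cap": cap,
                        "perm": perm,
                        "cell_type": r["cell_type"],
                        "accuracy": r["accuracy"],
                        "precision": r["precision"],
                        "f1": r["f1"],
                        "support": r["support"],
                    }
                )
    return pd.DataFrame(rows)
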