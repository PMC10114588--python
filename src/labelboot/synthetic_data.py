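"""Negative-binomial scRNA-seq count simulator with planted structure.

Generates datasets with the statistical features the benchmarking experiments
rely on: a handful of cell types at strongly imbalanced abundances, per-type
marker genes up-regulated by a multiplicative fold, pairs of closely related
types sharing a fraction of their markers, per-cell library-size variation,
and optional multi-batch sources with multiplicative lognormal batch effects.

Counts are drawn as x_cg ~ NB(mean = s_c * b_g * f_{t(c),g} * e_{batch(c),g},
dispersion theta_sim), where s_c is the cell's library factor, b_g a lognormal
per-gene baseline, f the marker fold, and e a per-(batch, gene) lognormal
factor. The gene-level structure (baseline, marker assignment) depends only on
(seed, n_genes, cell types, markers_per_type), so specs differing merely in
abundances or batch names — the mosaic setting — share identical biology.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .io_formats import ExpressionDataset

__all__ = [
    "SyntheticSpec",
    "GroundTruthBundle",
    "generate",
    "preset_pbmc_like",
    "preset_mosaic",
]

_STRUCTURE_TAG = 0x5EED
_BATCH_TAG = 0xBA7C
_CELL_TAG = 0xCE11


@dataclass
class SyntheticSpec:
    """Full parameterization of one simulated dataset.

    ``related_pairs`` entries (a, b, frac) make type b share ``frac`` of type
    a's markers at full fold — the mechanism behind boundary-mixing errors
    between closely related types. ``batches`` entries are
    (name, fraction_of_cells, batch_effect_sigma).
    """

    cell_types: list          # (name, abundance) pairs
    n_genes: int = 2000
    markers_per_type: int = 20
    marker_fold: float = 6.0
    related_pairs: list = field(default_factory=list)
    baseline_mean_logdist: tuple = (-1.0, 1.0)   # (mu, sigma) of ln baseline
    dispersion: float = 10.0                     # NB theta_sim
    libsize_logdist: tuple = (0.0, 0.3)          # (mu, sigma) of ln s_c
    batches: list = field(default_factory=lambda: [("batch0", 1.0, 0.0)])
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_types = [(str(n), int(a)) for n, a in self.cell_types]
        names = [n for n, _ in self.cell_types]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cell type names")
        if any(a < 1 for _, a in self.cell_types):
            raise ValueError("abundances must be >= 1")
        if self.markers_per_type * len(names) > self.n_genes:
            raise ValueError("markers_per_type * n_types exceeds n_genes")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        fracs = sum(f for _, f, _ in self.batches)
        if abs(fracs - 1.0) > 1e-9:
            raise ValueError("batch fractions must sum to 1")
        for a, b, frac in self.related_pairs:
            if a not in names or b not in names:
                raise ValueError(f"related pair ({a}, {b}) names unknown type")
            if not (0.0 <= frac <= 1.0):
                raise ValueError("shared_marker_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["cell_types"] = [tuple(x) for x in d["cell_types"]]
        d["related_pairs"] = [tuple(x) for x in d.get("related_pairs", [])]
        d["batches"] = [tuple(x) for x in d.get("batches", [])]
        d["baseline_mean_logdist"] = tuple(d["baseline_mean_logdist"])
        d["libsize_logdist"] = tuple(d["libsize_logdist"])
        return cls(**d)


@dataclass
class GroundTruthBundle:
    dataset: ExpressionDataset
    marker_map: dict          # type name -> list of marker gene ids
    batch_map: dict           # cell id -> batch name


def _tag_rng(seed: int, tag: int, extra: str = "") -> np.random.Generator:
    digest = hashlib.blake2s(extra.encode("utf-8"), digest_size=4).digest()
    return np.random.default_rng(
        np.random.SeedSequence(
            [int(seed), int(tag), int.from_bytes(digest, "little")]
        )
    )


def _structure(spec: SyntheticSpec):
    """Gene baseline + marker assignment, shared across same-seed sources."""
    rng = _tag_rng(spec.seed, _STRUCTURE_TAG)
    mu, sigma = spec.baseline_mean_logdist
    baseline = rng.lognormal(mu, sigma, size=spec.n_genes)
    names = [n for n, _ in spec.cell_types]
    perm = rng.permutation(spec.n_genes)
    markers: dict[str, list[int]] = {}
    k = spec.markers_per_type
    for i, name in enumerate(names):
        markers[name] = sorted(perm[i * k : (i + 1) * k].tolist())
    for a, b, frac in spec.related_pairs:
        n_shared = int(round(frac * k))
        if n_shared:
            shared = markers[a][:n_shared]
            own = [g for g in markers[b] if g not in shared]
            markers[b] = sorted(shared + own[: k - n_shared])
    return baseline, markers


def _batch_assignment(spec: SyntheticSpec, n_cells: int) -> np.ndarray:
    """Deterministic largest-remainder split of cells over batches."""
    fracs = np.asarray([f for _, f, _ in spec.batches])
    counts = np.floor(fracs * n_cells).astype(int)
    remainder = n_cells - counts.sum()
    order = np.argsort(-(fracs * n_cells - counts), kind="stable")
    for i in range(remainder):
        counts[order[i % len(counts)]] += 1
    names = [n for n, _, _ in spec.batches]
    rng = _tag_rng(spec.seed, _CELL_TAG, "batch-assignment")
    assignment = np.repeat(np.asarray(names, dtype=object), counts)
    return assignment[rng.permutation(n_cells)]


def generate(spec: SyntheticSpec) -> GroundTruthBundle:
    """Draw one dataset from the spec; bit-reproducible from ``spec.seed``."""
    baseline, markers = _structure(spec)
    gene_ids = np.asarray(
        [f"gene{g:05d}" for g in range(spec.n_genes)], dtype=object
    )
    names = [n for n, _ in spec.cell_types]
    fold = {n: np.ones(spec.n_genes) for n in names}
    for n in names:
        fold[n][markers[n]] = spec.marker_fold

    batch_sigma = {n: s for n, _, s in spec.batches}
    batch_factor = {}
    for bname in batch_sigma:
        if batch_sigma[bname] > 0:
            brng = _tag_rng(spec.seed, _BATCH_TAG, bname)
            batch_factor[bname] = brng.lognormal(
                0.0, batch_sigma[bname], size=spec.n_genes
            )
        else:
            batch_factor[bname] = np.ones(spec.n_genes)

    total = sum(a for _, a in spec.cell_types)
    batch_of_cell = _batch_assignment(spec, total)

    # cell-level streams are keyed by (type, batch composition): same-seed
    # specs share gene-level structure but draw independent cells, so a query
    # never duplicates reference cells
    batch_key = ",".join(n for n, _, _ in spec.batches)

    blocks = []
    labels = []
    cell_ids = []
    pos = 0
    lib_mu, lib_sigma = spec.libsize_logdist
    theta = spec.dispersion
    for name, abundance in spec.cell_types:
        crng = _tag_rng(spec.seed, _CELL_TAG, f"{name}|{batch_key}")
        s = crng.lognormal(lib_mu, lib_sigma, size=abundance)
        cell_batches = batch_of_cell[pos : pos + abundance]
        block = np.empty((abundance, spec.n_genes), dtype=np.int64)
        gene_mean_type = baseline * fold[name]
        for bname in dict.fromkeys(cell_batches.tolist()):
            rows = np.nonzero(cell_batches == bname)[0]
            mu = np.outer(s[rows], gene_mean_type * batch_factor[bname])
            p = theta / (theta + mu)
            block[rows] = crng.negative_binomial(theta, p)
        blocks.append(sp.csr_matrix(block))
        labels.extend([name] * abundance)
        cell_ids.extend(
            f"{b}:c{pos + i:06d}" for i, b in enumerate(cell_batches)
        )
        pos += abundance

    dataset = ExpressionDataset(
        counts=sp.vstack(blocks, format="csr"),
        cell_ids=np.asarray(cell_ids, dtype=object),
        gene_ids=gene_ids,
        labels=np.asarray(labels, dtype=object),
        batch=batch_of_cell,
    )
    marker_map = {
        n: [str(gene_ids[g]) for g in markers[n]] for n in names
    }
    batch_map = dict(zip(cell_ids, batch_of_cell.tolist()))
    return GroundTruthBundle(dataset, marker_map, batch_map)


#: abundances emulating a strongly imbalanced PBMC reference
PBMC_LIKE_TYPES = [
    ("CD4 T cell", 3000),
    ("Cytotoxic T cell", 2500),
    ("CD14+ monocyte", 1500),
    ("B cell", 1000),
    ("Natural killer cell", 600),
    ("CD16+ monocyte", 300),
    ("Dendritic cell", 150),
    ("Megakaryocyte", 60),
    ("Plasmacytoid dendritic cell", 38),
]


def preset_pbmc_like(seed: int = 0) -> SyntheticSpec:
    """Nine PBMC-style cell types, abundances 3000 down to 38, one closely
    related pair (CD14+ monocytes and dendritic cells share half their
    markers), single batch."""
    return SyntheticSpec(
        cell_types=list(PBMC_LIKE_TYPES),
        n_genes=2000,
        markers_per_type=20,
        marker_fold=6.0,
        related_pairs=[("CD14+ monocyte", "Dendritic cell", 0.5)],
        batches=[("10x", 1.0, 0.0)],
        seed=seed,
    )


def preset_mosaic(
    seed: int = 0, batch_effect_sigma: float = 0.3
) -> list[SyntheticSpec]:
    """Three sources sharing biology (same seed-derived structure) but with
    independent batch effects and different per-type abundances.

    The rarest type's pooled abundance roughly triples across sources
    (38 + 32 + 32 = 102), emulating the motivation for assembling mosaic
    references.
    """
    base = preset_pbmc_like(seed)
    scaled = {
        "dropseq": [
            ("CD4 T cell", 900),
            ("Cytotoxic T cell", 750),
            ("CD14+ monocyte", 450),
            ("B cell", 300),
            ("Natural killer cell", 180),
            ("CD16+ monocyte", 90),
            ("Dendritic cell", 45),
            ("Megakaryocyte", 30),
            ("Plasmacytoid dendritic cell", 32),
        ],
        "celseq": [
            ("CD4 T cell", 600),
            ("Cytotoxic T cell", 500),
            ("CD14+ monocyte", 300),
            ("B cell", 200),
            ("Natural killer cell", 120),
            ("CD16+ monocyte", 60),
            ("Dendritic cell", 30),
            ("Megakaryocyte", 20),
            ("Plasmacytoid dendritic cell", 32),
        ],
    }
    specs = [
        SyntheticSpec(
            cell_types=list(PBMC_LIKE_TYPES),
            n_genes=base.n_genes,
            markers_per_type=base.markers_per_type,
            marker_fold=base.marker_fold,
            related_pairs=list(base.related_pairs),
            batches=[("10x", 1.0, batch_effect_sigma)],
            seed=seed,
        )
    ]
    for bname, types in scaled.items():
        specs.append(
            SyntheticSpec(
                cell_types=types,
                n_genes=base.n_genes,
                markers_per_type=base.markers_per_type,
                marker_fold=base.marker_fold,
                related_pairs=list(base.related_pairs),
                batches=[(bname, 1.0, batch_effect_sigma)],
                seed=seed,
            )
        )
    return specs
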