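import numpy as np
import pytest
import scipy.sparse as sp

import labelboot as lb


@pytest.fixture
def tiny_dataset():
    """3 cells x 4 genes with hand-set counts."""
    counts = np.array(
        [
            [5, 0, 1, 0],
            [0, 2, 0, 0],
            [3, 0, 0, 7],
        ]
    )
    return lb.ExpressionDataset(
        counts=sp.csr_matrix(counts),
        cell_ids=np.array(["c1", "c2", "c3"], dtype=object),
        gene_ids=np.array(["g1", "g2", "g3", "g4"], dtype=object),
        labels=np.array(["A", "B", "A"], dtype=object),
    )


def small_bundle(
    abundances=(("A", 120), ("B", 90), ("C", 40)),
    query_abundances=(("A", 30), ("B", 30), ("C", 20)),
    n_genes=300,
    markers_per_type=10,
    marker_fold=6.0,
    related_pairs=(),
    seed=0,
    dispersion=10.0,
):
    """Matched (reference, query) datasets sharing planted structure."""
    common = dict(
        n_genes=n_genes,
        markers_per_type=markers_per_type,
        marker_fold=marker_fold,
        related_pairs=list(related_pairs),
        dispersion=dispersion,
        seed=seed,
    )
    ref = lb.generate(
        lb.SyntheticSpec(cell_types=list(abundances), **common)
    )
    qry = lb.generate(
        lb.SyntheticSpec(
            cell_types=list(query_abundances),
            batches=[("query", 1.0, 0.0)],
            **common,
        )
    )
    return ref, qry


def processed_pair(ref_ds, qry_ds, n_hvgs=150):
    hvgs = lb.select_hvgs_pearson_residuals(ref_ds, n_hvgs)
    return lb.preprocess(ref_ds, hvg_ids=hvgs), lb.preprocess(qry_ds, hvg_ids=hvgs)


def truth_map(ds):
    return dict(zip(ds.cell_ids.astype(str), ds.labels.astype(str)))


@pytest.fixture
def small_ref_query():
    ref, qry = small_bundle(seed=7)
    ref_pm, qry_pm = processed_pair(ref.dataset, qry.dataset)
    return ref, qry, ref_pm, qry_pm
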