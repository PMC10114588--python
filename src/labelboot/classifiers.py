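"""From-scratch label-transfer classifiers behind a uniform contract.

Four algorithms, all consuming :class:`~labelboot.preprocessing.ProcessedMatrix`
pairs with identical gene columns and emitting per-cell
:class:`~labelboot.io_formats.LabelPrediction` lists:

``singler_like``
    Iterative Spearman-correlation elimination: per query cell, repeatedly score
    every surviving cell type by an aggregate of Spearman correlations to its
    reference cells (computed on genes that discriminate the surviving types),
    drop the worst-scoring type plus every type falling more than a margin
    below the top, and stop when two types remain.
``cca_mnn``
    Canonical-correlation embedding of reference and query into a shared space
    (exact SVD of the standardized cross-product matrix), followed by a
    majority vote over mutual nearest neighbors.
``toppair_forest``
    Top-pair transform (binary gene-vs-gene comparisons on discriminative
    pairs) feeding a random forest; optional random-profile pseudo-cells give
    the forest an explicit reject class.
``centroid``
    Per-type centroid of the processed reference; nearest centroid by Pearson
    correlation. Fast baseline.

These are lightweight reimplementations of the published algorithms' core
ideas, not byte-compatible ports. Ties are everywhere broken by lexicographic
label order; cells flagged as having no counts on the gene set are emitted as
UNASSIGNED with confidence 0.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from .io_formats import UNASSIGNED, LabelPrediction
from .preprocessing import ProcessedMatrix

__all__ = [
    "ClassifierSpec",
    "predict",
    "predict_singler_like",
    "predict_cca_mnn",
    "predict_toppair_forest",
    "predict_centroid",
    "CLASSIFIERS",
]

_EPS = 1e-12

#: pseudo-label for random profiles inside the top-pair forest
_RANDOM_CLASS = "__random__"


@dataclass
class ClassifierSpec:
    """Name + parameters + seed identifying a classifier run."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.name!r}; "
                f"choose from {sorted(CLASSIFIERS)}"
            )


ClassifierLike = Union[
    ClassifierSpec,
    Callable[..., list],  # (reference, ref_labels, query, seed) -> predictions
]


def predict(
    classifier: ClassifierLike,
    reference: ProcessedMatrix,
    ref_labels: Sequence[str],
    query: ProcessedMatrix,
    seed: Optional[int] = None,
) -> list[LabelPrediction]:
    """Dispatch to a named classifier or a user-supplied callable."""
    if isinstance(classifier, ClassifierSpec):
        fn = CLASSIFIERS[classifier.name]
        return fn(
            reference,
            ref_labels,
            query,
            params=classifier.params,
            seed=classifier.seed if seed is None else seed,
        )
    return classifier(reference, ref_labels, query, 0 if seed is None else seed)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _check_shared_genes(reference: ProcessedMatrix, query: ProcessedMatrix) -> None:
    if len(reference.hvg_ids) == 0:
        raise ValueError("empty gene set")
    if len(reference.hvg_ids) != len(query.hvg_ids) or not np.array_equal(
        reference.hvg_ids, query.hvg_ids
    ):
        raise ValueError("reference and query must share identical gene columns")


def _split_valid(pm: ProcessedMatrix) -> np.ndarray:
    """Indices of cells that carry signal (not flagged all-zero)."""
    return np.nonzero(~pm.zero_cells)[0]


def _centered_ranks(X: np.ndarray) -> np.ndarray:
    """Row-wise ranks, centered and L2-normalized (zero rows stay zero)."""
    R = rankdata(X, axis=1).astype(np.float64)
    R -= R.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(R, axis=1)
    ok = norms > 0
    R[ok] /= norms[ok, None]
    R[~ok] = 0.0
    return R


def _majority(labels: Sequence[str]) -> tuple[str, float]:
    """Most common label, ties lexicographic; returns (label, vote fraction)."""
    counts: dict[str, int] = defaultdict(int)
    for lab in labels:
        counts[lab] += 1
    best = min(counts, key=lambda l: (-counts[l], l))
    return best, counts[best] / len(labels)


# ---------------------------------------------------------------------------
# singler_like: iterative Spearman elimination
# ---------------------------------------------------------------------------

def _discriminative_genes(
    medians: dict, types: Sequence[str], per_type: int
) -> np.ndarray:
    """Union over surviving types of the top genes by median-difference score.

    Per type t the score of gene g is (median of g within t) minus the max of
    g's medians over the other surviving types; genes ranked by descending
    score, ties by ascending column index. ``medians`` maps each type to its
    per-gene median vector (precomputed once per reference). Deterministic and
    cell-order invariant.
    """
    n_genes = len(next(iter(medians.values())))
    chosen: set[int] = set()
    for t in sorted(types):
        others = np.max([medians[u] for u in types if u != t], axis=0)
        score = medians[t] - others
        # sort by descending score, ties by ascending column index
        order = np.lexsort((np.arange(n_genes), -score))
        chosen.update(order[:per_type].tolist())
    return np.asarray(sorted(chosen), dtype=int)


def _eliminate(
    types: Sequence[str], scores: np.ndarray, margin: float
) -> list[str]:
    """One elimination round: drop the lowest-scoring type and every type more
    than ``margin`` below the top. If that would leave fewer than two types,
    keep the top two (score desc, ties by ascending label)."""
    types = list(types)
    top = scores.max()
    min_s = scores.min()
    lowest = max(t for t, s in zip(types, scores) if s == min_s)
    removed = {lowest} | {t for t, s in zip(types, scores) if s < top - margin}
    survivors = [t for t in types if t not in removed]
    if len(survivors) < 2:
        ranked = sorted(zip(types, scores), key=lambda ts: (-ts[1], ts[0]))
        survivors = sorted([ranked[0][0], ranked[1][0]])
    return survivors


def predict_singler_like(
    reference: ProcessedMatrix,
    ref_labels: Sequence[str],
    query: ProcessedMatrix,
    params: Optional[dict] = None,
    seed: int = 0,
) -> list[LabelPrediction]:
    """Iterative Spearman-correlation elimination (SingleR-style), batched.

    Per round and per set of surviving cell types: select discriminative genes
    among those types, Spearman-correlate each query cell with every reference
    cell of those types on that gene set, aggregate per type (80th percentile
    of per-cell correlations by default), then eliminate. Query cells sharing
    the same surviving-type set are processed together, which makes the
    per-cell procedure tractable on thousands of reference cells.

    Confidence is artifact-defined: (s1 - s2) / max(s1 - s_min, eps) clipped to
    [0, 1], where s1, s2 are the two finalists' scores and s_min is the lowest
    per-type score this cell saw in its first round.
    """
    p = {"margin": 0.05, "genes_per_type": 50, "quantile": 0.8}
    p.update(params or {})
    _check_shared_genes(reference, query)
    ref_labels = np.asarray(ref_labels, dtype=object)
    ref_idx = _split_valid(reference)
    rvals = reference.values[ref_idx]
    rlabs = ref_labels[ref_idx]
    all_types = sorted(set(map(str, rlabs)))
    if len(all_types) < 2:
        raise ValueError("reference must contain at least 2 distinct labels")

    nq = query.n_cells
    out_label = np.full(nq, UNASSIGNED, dtype=object)
    out_conf = np.zeros(nq)
    s_first_min = np.full(nq, np.nan)

    # per-type medians over all genes, computed once: gene selection per
    # surviving-type set then reduces to a max over cached vectors
    medians = {t: np.median(rvals[rlabs == t], axis=0) for t in all_types}

    # worklist keyed by surviving-type set, processed in decreasing set size:
    # elimination strictly shrinks the set, so every cell bound for a given
    # type set has arrived before that set is scored, and each distinct set
    # is ranked and correlated exactly once
    pending: dict[frozenset, list] = defaultdict(list)
    pending[frozenset(all_types)] = list(_split_valid(query))
    for size in range(len(all_types), 1, -1):
        for tset in sorted(
            (t for t in pending if len(t) == size),
            key=lambda t: sorted(t),
        ):
            qidx = np.asarray(pending.pop(tset), dtype=int)
            if qidx.size == 0:
                continue
            types = sorted(tset)
            genes = _discriminative_genes(medians, types, p["genes_per_type"])
            mask = np.isin(rlabs, types)
            R = _centered_ranks(rvals[np.ix_(np.nonzero(mask)[0], genes)])
            Q = _centered_ranks(query.values[np.ix_(qidx, genes)])
            corr = Q @ R.T
            sub_labs = rlabs[mask]
            scores = np.column_stack(
                [
                    np.percentile(
                        corr[:, sub_labs == t], p["quantile"] * 100, axis=1
                    )
                    for t in types
                ]
            )
            fresh = np.isnan(s_first_min[qidx])
            s_first_min[qidx[fresh]] = scores[fresh].min(axis=1)
            if len(types) == 2:
                # final round: the higher-scoring finalist wins
                for row, qi in enumerate(qidx):
                    s = scores[row]
                    winner = 0 if s[0] >= s[1] else 1
                    if s[0] == s[1]:
                        winner = 0  # types sorted: lexicographic tie-break
                    s1, s2 = s[winner], s[1 - winner]
                    denom = max(s1 - s_first_min[qi], _EPS)
                    out_label[qi] = types[winner]
                    out_conf[qi] = float(np.clip((s1 - s2) / denom, 0.0, 1.0))
            else:
                for row, qi in enumerate(qidx):
                    surv = _eliminate(types, scores[row], p["margin"])
                    pending[frozenset(surv)].append(qi)

    return [
        LabelPrediction(str(cid), str(lab), float(conf))
        for cid, lab, conf in zip(query.cell_ids, out_label, out_conf)
    ]


# ---------------------------------------------------------------------------
# cca_mnn: shared CCA embedding + mutual-nearest-neighbor majority vote
# ---------------------------------------------------------------------------

def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def predict_cca_mnn(
    reference: ProcessedMatrix,
    ref_labels: Sequence[str],
    query: ProcessedMatrix,
    params: Optional[dict] = None,
    seed: int = 0,
) -> list[LabelPrediction]:
    """CCA embedding + mutual-nearest-neighbor label transfer (Seurat-style).

    Both matrices are column-standardized; the SVD of the cross-product
    ``X_ref @ X_query.T`` yields paired embeddings (left/right singular
    vectors weighted by their singular values — so weakly correlated
    components contribute little — then L2 row-scaled). Each query cell takes
    the
    most common label among its mutual nearest neighbors (k per side,
    Euclidean); confidence is the winning vote fraction. Cells with no mutual
    partner fall back to their single nearest reference neighbor with
    confidence 0.
    """
    p = {"n_cca": 20, "k": 5}
    p.update(params or {})
    if p["n_cca"] < 1:
        raise ValueError("n_cca must be >= 1")
    _check_shared_genes(reference, query)
    ref_labels = np.asarray(ref_labels, dtype=object)
    ridx = _split_valid(reference)
    qidx = _split_valid(query)
    out: dict[int, LabelPrediction] = {}
    if qidx.size:
        Xr = _standardize_columns(reference.values[ridx])
        Xq = _standardize_columns(query.values[qidx])
        C = Xr @ Xq.T
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        if s.size == 0 or s[0] <= _EPS:
            raise ValueError("degenerate (rank-0) cross-product matrix")
        k_cca = int(min(p["n_cca"], (s > _EPS * s[0]).sum()))
        re_emb = U[:, :k_cca] * s[:k_cca]
        qe_emb = Vt[:k_cca].T * s[:k_cca]
        for emb in (re_emb, qe_emb):
            norms = np.linalg.norm(emb, axis=1)
            ok = norms > 0
            emb[ok] /= norms[ok, None]
        k = int(min(p["k"], len(ridx), len(qidx)))
        nn_ref = NearestNeighbors(n_neighbors=k).fit(re_emb)
        q2r = nn_ref.kneighbors(qe_emb, return_distance=False)
        nn_qry = NearestNeighbors(n_neighbors=k).fit(qe_emb)
        r2q = nn_qry.kneighbors(re_emb, return_distance=False)
        r2q_sets = [set(row.tolist()) for row in r2q]
        labs = ref_labels[ridx]
        for qi_local, qi in enumerate(qidx):
            partners = [
                r for r in q2r[qi_local] if qi_local in r2q_sets[r]
            ]
            if partners:
                lab, frac = _majority([str(labs[r]) for r in partners])
                out[qi] = LabelPrediction(str(query.cell_ids[qi]), lab, frac)
            else:
                lab = str(labs[q2r[qi_local][0]])
                out[qi] = LabelPrediction(str(query.cell_ids[qi]), lab, 0.0)
    return [
        out.get(i, LabelPrediction(str(query.cell_ids[i]), UNASSIGNED, 0.0))
        for i in range(query.n_cells)
    ]


# ---------------------------------------------------------------------------
# toppair_forest: top-pair transform + random forest
# ---------------------------------------------------------------------------

def _select_pairs(
    values: np.ndarray,
    labels: np.ndarray,
    genes_per_type: int,
    opponent_top: int,
    max_pairs: int,
) -> list[tuple[int, int]]:
    """Discriminative gene pairs: each of a type's top genes (by mean
    difference vs the rest) against the ``opponent_top`` best genes of every
    other type. Pairs are emitted in gene-rank order, round-robin over types,
    so the ``max_pairs`` cap cuts every type's weakest pairs rather than
    whole types. Deterministic."""
    types = sorted(set(map(str, labels)))
    top_genes: dict[str, list[int]] = {}
    for t in types:
        mask = labels == t
        diff = values[mask].mean(axis=0) - values[~mask].mean(axis=0)
        order = sorted(range(values.shape[1]), key=lambda g: (-diff[g], g))
        top_genes[t] = order[:genes_per_type]
    pairs: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for rank in range(genes_per_type):
        for t in types:
            if rank >= len(top_genes[t]):
                continue
            g = top_genes[t][rank]
            for u in types:
                if u == t:
                    continue
                for j in range(min(opponent_top, len(top_genes[u]))):
                    pair = (g, top_genes[u][j])
                    if pair[0] != pair[1] and pair not in seen:
                        seen.add(pair)
                        pairs.append(pair)
                    if len(pairs) >= max_pairs:
                        return pairs
    return pairs


def predict_toppair_forest(
    reference: ProcessedMatrix,
    ref_labels: Sequence[str],
    query: ProcessedMatrix,
    params: Optional[dict] = None,
    seed: int = 0,
) -> list[LabelPrediction]:
    """Top-pair transform + random forest (SingleCellNet-style).

    Cells are encoded as binary vectors ``[x_g1 > x_g2]`` over discriminative
    gene pairs and classified by a seeded random forest. With ``n_rand > 0``,
    shuffled-expression pseudo-cells form an explicit reject class: query cells
    classified as that class are emitted UNASSIGNED (and scored as false
    predictions downstream). Confidence is the forest's vote fraction for the
    winning class. Reference rows are sorted by cell id before training so the
    result is invariant to reference cell order.
    """
    p = {
        "genes_per_type": 25,
        "opponent_top": 3,
        "max_pairs": 500,
        "n_trees": 200,
        "n_rand": 0,
    }
    p.update(params or {})
    _check_shared_genes(reference, query)
    ref_labels = np.asarray(ref_labels, dtype=object)
    ridx = _split_valid(reference)
    order = ridx[np.argsort(reference.cell_ids[ridx].astype(str), kind="stable")]
    rvals = reference.values[order]
    rlabs = ref_labels[order].astype(str)
    if len(set(rlabs)) < 2 and p["n_rand"] == 0:
        raise ValueError("reference must contain at least 2 distinct labels")
    pairs = _select_pairs(
        rvals, rlabs, p["genes_per_type"], p["opponent_top"], p["max_pairs"]
    )
    if not pairs:
        raise ValueError("no gene pairs selectable")
    g1 = np.asarray([a for a, _ in pairs])
    g2 = np.asarray([b for _, b in pairs])

    X_train = rvals[:, g1] > rvals[:, g2]
    y_train = list(rlabs)
    if p["n_rand"] > 0:
        rng = np.random.default_rng(seed)
        n, g = rvals.shape
        rand_rows = rvals[
            rng.integers(0, n, size=(int(p["n_rand"]), g)), np.arange(g)
        ]
        X_train = np.vstack([X_train, rand_rows[:, g1] > rand_rows[:, g2]])
        y_train = y_train + [_RANDOM_CLASS] * int(p["n_rand"])

    forest = RandomForestClassifier(
        n_estimators=int(p["n_trees"]), random_state=int(seed) % (2**31)
    )
    forest.fit(X_train, y_train)

    qidx = _split_valid(query)
    out: dict[int, LabelPrediction] = {}
    if qidx.size:
        qv = query.values[qidx]
        proba = forest.predict_proba(qv[:, g1] > qv[:, g2])
        classes = forest.classes_  # sorted, so argmax ties are lexicographic
        for row, qi in enumerate(qidx):
            w = int(np.argmax(proba[row]))
            lab = str(classes[w])
            conf = float(proba[row, w])
            if lab == _RANDOM_CLASS:
                lab = UNASSIGNED
            out[qi] = LabelPrediction(str(query.cell_ids[qi]), lab, conf)
    return [
        out.get(i, LabelPrediction(str(query.cell_ids[i]), UNASSIGNED, 0.0))
        for i in range(query.n_cells)
    ]


# ---------------------------------------------------------------------------
# centroid: nearest per-type centroid by Pearson correlation
# ---------------------------------------------------------------------------

def predict_centroid(
    reference: ProcessedMatrix,
    ref_labels: Sequence[str],
    query: ProcessedMatrix,
    params: Optional[dict] = None,
    seed: int = 0,
) -> list[LabelPrediction]:
    """Nearest-centroid baseline.

    Each type's centroid is the mean of its processed reference cells; a query
    cell takes the label of the most Pearson-correlated centroid. Confidence is
    the winner's softmax probability over correlations (temperature 0.1). A
    single-label reference is permitted (always predicted, confidence 1).
    """
    p = {"temperature": 0.1}
    p.update(params or {})
    _check_shared_genes(reference, query)
    ref_labels = np.asarray(ref_labels, dtype=object)
    ridx = _split_valid(reference)
    rvals = reference.values[ridx]
    rlabs = ref_labels[ridx].astype(str)
    types = sorted(set(rlabs))
    if not types:
        raise ValueError("reference is empty after dropping zero cells")
    centroids = np.vstack([rvals[rlabs == t].mean(axis=0) for t in types])
    cc = centroids - centroids.mean(axis=1, keepdims=True)
    cnorm = np.linalg.norm(cc, axis=1)
    cnorm[cnorm == 0] = 1.0
    cc /= cnorm[:, None]

    qidx = _split_valid(query)
    out: dict[int, LabelPrediction] = {}
    if qidx.size:
        qv = query.values[qidx]
        qc = qv - qv.mean(axis=1, keepdims=True)
        qn = np.linalg.norm(qc, axis=1)
        qn[qn == 0] = 1.0
        qc /= qn[:, None]
        corr = qc @ cc.T
        if len(types) == 1:
            for qi in qidx:
                out[qi] = LabelPrediction(str(query.cell_ids[qi]), types[0], 1.0)
        else:
            z = corr / p["temperature"]
            z -= z.max(axis=1, keepdims=True)
            soft = np.exp(z)
            soft /= soft.sum(axis=1, keepdims=True)
            for row, qi in enumerate(qidx):
                w = int(np.argmax(corr[row]))  # first occurrence: lexicographic
                out[qi] = LabelPrediction(
                    str(query.cell_ids[qi]), types[w], float(soft[row, w])
                )
    return [
        out.get(i, LabelPrediction(str(query.cell_ids[i]), UNASSIGNED, 0.0))
        for i in range(query.n_cells)
    ]


CLASSIFIERS: dict[str, Callable] = {
    "singler_like": predict_singler_like,
    "cca_mnn": predict_cca_mnn,
    "toppair_forest": predict_toppair_forest,
    "centroid": predict_centroid,
}
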