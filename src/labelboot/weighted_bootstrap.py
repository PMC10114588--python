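"""Weighted bootstrap-annotation: the core label-transfer scheme.

The idea: rather than classifying the query once against a (possibly severely
imbalanced) reference, build one subset per cell type — subset j capped at
type j's own abundance — classify the query against each subset, and weight
each subset's vote by how close the predicted label's abundance in the *full*
reference is to that subset's cap:

    w(l, r_j) = 1 / (|n(l) - max(r_j)| + 1)

where n(l) is the number of cells annotated l in the full reference and
max(r_j) is subset j's per-type cap. A prediction is thus trusted most when it
comes from the subset in which its cell type is best represented without being
overshadowed: a vote for a 38-cell type from the cap-38 subset carries weight
1, the same vote from a cap-3000 subset carries ~1/3000. Summing weights per
label over all subsets (and, optionally, over independent series replicates)
and taking the argmax yields the final annotation.

The scheme is classifier-agnostic: any function with the uniform classifier
contract can supply the per-subset votes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .classifiers import ClassifierLike, predict
from .io_formats import UNASSIGNED, ExpressionDataset, LabelPrediction
from .preprocessing import (
    DEFAULT_N_HVGS,
    ProcessedMatrix,
    preprocess,
    select_hvgs_pearson_residuals,
)
from .reference_design import build_subset_series

__all__ = [
    "compute_weight",
    "BootstrapResult",
    "run_weighted_bootstrap",
    "compare_bootstrap_vs_full",
]


def compute_weight(n_label: int, cap: int, mode: str = "absolute") -> float:
    """Vote weight for a predicted label with full-reference abundance
    ``n_label``, cast by a subset with per-type cap ``cap``.

    ``mode="absolute"`` (default) returns ``1 / (|n_label - cap| + 1)``:
    strictly decreasing in the abundance-cap distance, and exactly 1 iff
    ``n_label == cap``. ``mode="strict"`` evaluates the literal signed form
    ``1 / (n_label - cap + 1)`` and raises whenever the denominator is not
    positive.
    """
    if n_label < 1 or cap < 1:
        raise ValueError("n_label and cap must be positive")
    if mode == "absolute":
        return 1.0 / (abs(int(n_label) - int(cap)) + 1)
    if mode == "strict":
        denom = int(n_label) - int(cap) + 1
        if denom <= 0:
            raise ValueError(
                f"strict-mode weight undefined: n_label={n_label}, cap={cap} "
                f"give non-positive denominator {denom}"
            )
        return 1.0 / denom
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class BootstrapResult:
    """Votes, summed weights, and the aggregated per-cell annotation."""

    votes: pd.DataFrame        # cell_id, replicate, subset_type, cap, label, weight
    score_table: pd.DataFrame  # index cell_id, one column per label: summed weight
    predictions: list          # LabelPrediction per query cell (conf = stability)
    n_boot: int
    ties: list                 # cell_ids whose argmax was decided by tie-break


def _aggregate(
    cell_ids: Sequence[str], votes: pd.DataFrame, labels: Sequence[str]
) -> tuple[pd.DataFrame, list[LabelPrediction], list[str]]:
    labels = sorted(labels)
    score = pd.DataFrame(
        0.0, index=list(cell_ids), columns=labels
    )
    real = votes[votes["label"] != UNASSIGNED]
    if len(real):
        summed = real.groupby(["cell_id", "label"])["weight"].sum()
        for (cid, lab), w in summed.items():
            score.at[cid, lab] = w
    preds, ties = [], []
    totals = score.sum(axis=1)
    for cid in cell_ids:
        row = score.loc[cid]
        if totals[cid] <= 0:
            preds.append(LabelPrediction(str(cid), UNASSIGNED, 0.0))
            continue
        top = row.max()
        winners = [l for l in labels if row[l] == top]
        if len(winners) > 1:
            ties.append(str(cid))
        winner = winners[0]  # labels sorted: lexicographic tie-break
        stability = float(top / totals[cid])
        preds.append(LabelPrediction(str(cid), winner, stability))
    return score, preds, ties


def run_weighted_bootstrap(
    query: ExpressionDataset,
    reference: ExpressionDataset,
    classifier: ClassifierLike,
    n_boot: int = 20,
    seed: int = 0,
    n_hvgs: int = DEFAULT_N_HVGS,
    weight_mode: str = "absolute",
    processed: Optional[tuple[ProcessedMatrix, ProcessedMatrix]] = None,
) -> BootstrapResult:
    """Classify the query against every subset of ``n_boot`` subset series and
    aggregate the weighted votes.

    Per replicate b (seeds ``seed + b``): build a subset series (one subset per
    cell type, capped at that type's full-reference abundance), classify the
    query on each subset, and weight each per-cell vote by
    :func:`compute_weight` of (the predicted label's full-reference abundance,
    the subset's cap). Weights are summed per label across all subsets and
    replicates; the argmax label wins (lexicographic tie-break, ties logged).
    UNASSIGNED votes carry zero weight and can never win; a cell with only
    UNASSIGNED votes is emitted as UNASSIGNED.

    The per-cell confidence reported is a stability score: the winner's summed
    weight over the cell's total summed weight.

    ``processed`` may supply pre-computed (reference, query) ProcessedMatrix
    pairs to skip preprocessing (HVGs are otherwise selected on the reference
    alone).
    """
    if reference.labels is None:
        raise ValueError("reference must be labeled")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    abundances = reference.label_counts()
    if len(abundances) < 2:
        raise ValueError("reference needs at least 2 cell types")
    if processed is None:
        hvgs = select_hvgs_pearson_residuals(reference, n_hvgs)
        ref_pm = preprocess(reference, hvg_ids=hvgs)
        qry_pm = preprocess(query, hvg_ids=hvgs)
    else:
        ref_pm, qry_pm = processed

    vote_rows = []
    qids = qry_pm.cell_ids.astype(str)
    for b in range(n_boot):
        series = build_subset_series(reference, seed=seed + b)
        for subset, subset_type in zip(series.subsets, series.type_order):
            preds = predict(
                classifier,
                ref_pm.subset(subset.cell_indices),
                reference.labels[subset.cell_indices],
                qry_pm,
                seed=subset.seed % (2**31),
            )
            for p in preds:
                w = (
                    0.0
                    if p.label == UNASSIGNED
                    else compute_weight(
                        abundances[p.label], subset.cap, mode=weight_mode
                    )
                )
                vote_rows.append(
                    {
                        "cell_id": p.cell_id,
                        "replicate": b,
                        "subset_type": subset_type,
                        "cap": subset.cap,
                        "label": p.label,
                        "weight": w,
                    }
                )
    votes = pd.DataFrame(vote_rows)
    score, preds, ties = _aggregate(qids, votes, sorted(abundances))
    return BootstrapResult(
        votes=votes, score_table=score, predictions=preds,
        n_boot=n_boot, ties=ties,
    )


def compare_bootstrap_vs_full(
    query: ExpressionDataset,
    reference: ExpressionDataset,
    classifier: ClassifierLike,
    n_boot: int = 20,
    seed: int = 0,
    n_hvgs: int = DEFAULT_N_HVGS,
    weight_mode: str = "absolute",
) -> dict:
    """Run both the plain full-reference prediction and the weighted bootstrap
    and tabulate per-type metric deltas.

    Returns a dict with keys ``full_report``, ``bootstrap_report``
    (:class:`~labelboot.evaluation.EvaluationReport`), ``delta`` (tidy frame:
    cell_type, metric, full, bootstrap, delta) and ``per_cell`` (cell_id,
    truth, full_label, bootstrap_label, vote_correctness = unweighted fraction
    of per-subset votes matching the truth).
    """
    if query.labels is None:
        raise ValueError("query must carry ground-truth labels")
    hvgs = select_hvgs_pearson_residuals(reference, n_hvgs)
    ref_pm = preprocess(reference, hvg_ids=hvgs)
    qry_pm = preprocess(query, hvg_ids=hvgs)
    truth = dict(zip(query.cell_ids.astype(str), query.labels.astype(str)))

    full_preds = predict(
        classifier, ref_pm, reference.labels, qry_pm, seed=seed % (2**31)
    )
    boot = run_weighted_bootstrap(
        query, reference, classifier, n_boot=n_boot, seed=seed,
        weight_mode=weight_mode, processed=(ref_pm, qry_pm),
    )
    full_report = evaluation.evaluate(full_preds, truth)
    boot_report = evaluation.evaluate(boot.predictions, truth)

    delta_rows = []
    fc = full_report.per_class.set_index("cell_type")
    bc = boot_report.per_class.set_index("cell_type")
    for t in sorted(set(fc.index) | set(bc.index)):
        for metric in ("accuracy", "precision", "f1"):
            f = float(fc.loc[t, metric]) if t in fc.index else np.nan
            b = float(bc.loc[t, metric]) if t in bc.index else np.nan
            delta_rows.append(
                {
                    "cell_type": t,
                    "metric": metric,
                    "full": f,
                    "bootstrap": b,
                    "delta": b - f,
                }
            )
    vc = (
        boot.votes.assign(
            correct=lambda d: d.apply(
                lambda r: float(r["label"] == truth[r["cell_id"]]), axis=1
            )
        )
        .groupby("cell_id")["correct"]
        .mean()
    )
    full_by_id = {p.cell_id: p.label for p in full_preds}
    boot_by_id = {p.cell_id: p.label for p in boot.predictions}
    per_cell = pd.DataFrame(
        {
            "cell_id": list(truth),
            "truth": [truth[c] for c in truth],
            "full_label": [full_by_id[c] for c in truth],
            "bootstrap_label": [boot_by_id[c] for c in truth],
            "vote_correctness": [float(vc[c]) for c in truth],
        }
    )
    return {
        "full_report": full_report,
        "bootstrap_report": boot_report,
        "delta": pd.DataFrame(delta_rows),
        "per_cell": per_cell,
    }
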