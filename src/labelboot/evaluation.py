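"""Per-cell-type scoring, boxplot statistics, and confidence calibration.

Terminology: per-type "accuracy" here means recall/sensitivity — the fraction
of that type's query cells that were recovered — which is how the cap-sweep
accuracy-vs-precision trade-off is framed. Per-type precision is the fraction
of cells predicted as the type that truly are it. UNASSIGNED predictions count
as false for their true class and occupy their own confusion column, so they
never enter a real class's precision denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from .io_formats import UNASSIGNED, LabelPrediction

__all__ = [
    "EvaluationReport",
    "BoxplotStats",
    "CalibrationReport",
    "evaluate",
    "boxplot_stats",
    "confidence_calibration",
]


@dataclass
class EvaluationReport:
    confusion: pd.DataFrame   # true types x predicted labels (+ UNASSIGNED)
    per_class: pd.DataFrame   # cell_type, accuracy, precision, f1, support
    macro_f1: float
    micro_f1: float           # == micro accuracy for single-label prediction

    def to_dict(self) -> dict:
        return {
            "macro_f1": self.macro_f1,
            "micro_f1": self.micro_f1,
            "per_class": self.per_class.to_dict(orient="records"),
            "confusion": {
                "true_labels": self.confusion.index.tolist(),
                "predicted_labels": self.confusion.columns.tolist(),
                "matrix": self.confusion.to_numpy().tolist(),
            },
        }


def evaluate(
    predictions: Sequence[LabelPrediction],
    truth: Mapping[str, str],
) -> EvaluationReport:
    """Confusion matrix plus per-class accuracy (recall), precision, F1.

    ``truth`` maps cell_id -> true label; its key set must equal the predicted
    cell_id set. macro F1 is the unweighted mean of per-class F1 over true
    classes; micro F1 equals the plain fraction of correctly labeled cells.
    """
    pred_map = {p.cell_id: p.label for p in predictions}
    if set(pred_map) != set(truth):
        raise ValueError("prediction and truth cell_id sets differ")
    if len(pred_map) != len(predictions):
        raise ValueError("duplicate cell_ids in predictions")
    true_labels = sorted(set(map(str, truth.values())))
    pred_labels = sorted(set(map(str, pred_map.values())) | set(true_labels))
    if UNASSIGNED in pred_labels:
        pred_labels = [l for l in pred_labels if l != UNASSIGNED] + [UNASSIGNED]
    confusion = pd.DataFrame(
        0, index=true_labels, columns=pred_labels, dtype=int
    )
    for cid, t in truth.items():
        confusion.at[str(t), str(pred_map[cid])] += 1

    rows = []
    f1s = []
    for t in true_labels:
        support = int(confusion.loc[t].sum())
        tp = int(confusion.at[t, t]) if t in confusion.columns else 0
        predicted_n = int(confusion[t].sum()) if t in confusion.columns else 0
        acc = tp / support if support else 0.0
        prec = tp / predicted_n if predicted_n else 0.0
        f1 = 2 * prec * acc / (prec + acc) if (prec + acc) > 0 else 0.0
        rows.append(
            {
                "cell_type": t,
                "accuracy": acc,
                "precision": prec,
                "f1": f1,
                "support": support,
            }
        )
        f1s.append(f1)
    micro = sum(
        int(confusion.at[t, t]) for t in true_labels if t in confusion.columns
    ) / len(truth)
    return EvaluationReport(
        confusion=confusion,
        per_class=pd.DataFrame(rows),
        macro_f1=float(np.mean(f1s)) if f1s else 0.0,
        micro_f1=float(micro),
    )


@dataclass
class BoxplotStats:
    """Tukey boxplot summary with whiskers clamped to actual data."""

    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def boxplot_stats(values: Sequence[float]) -> BoxplotStats:
    """Quartiles (linear interpolation), 1.5*IQR whiskers clamped to the data,
    and the points outside them."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("boxplot_stats needs at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("boxplot_stats requires finite values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotStats(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=np.sort(v[(v < lo_fence) | (v > hi_fence)]),
        n=int(v.size),
    )


@dataclass
class CalibrationReport:
    """Per predicted class: confidence distributions of true vs false
    predictions and a rank-sum comparison between them."""

    per_class: dict = field(default_factory=dict)
    alpha: float = 0.05

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for cls, rec in sorted(self.per_class.items()):
            rows.append(
                {
                    "predicted_class": cls,
                    "n_true": rec["n_true"],
                    "n_false": rec["n_false"],
                    "median_true": (
                        rec["true_stats"].median if rec["true_stats"] else np.nan
                    ),
                    "median_false": (
                        rec["false_stats"].median if rec["false_stats"] else np.nan
                    ),
                    "p_value": rec["p_value"],
                    "significant": rec["significant"],
                }
            )
        return pd.DataFrame(rows)


def confidence_calibration(
    predictions: Sequence[LabelPrediction],
    truth: Mapping[str, str],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> CalibrationReport:
    """Split each predicted class's confidences into true/false groups and test
    whether they differ.

    The two-sided Wilcoxon rank-sum test runs when both groups have at least
    two members; otherwise the p-value is absent (None). ``bh_correct``
    applies Benjamini-Hochberg across classes before flagging significance
    (off by default).
    """
    conf_preds = [p for p in predictions if p.confidence is not None]
    if not conf_preds:
        raise ValueError("no predictions carry confidence scores")
    groups: dict[str, dict[str, list[float]]] = {}
    for p in conf_preds:
        if p.cell_id not in truth:
            raise ValueError(f"no ground truth for cell {p.cell_id!r}")
        g = groups.setdefault(p.label, {"true": [], "false": []})
        g["true" if str(truth[p.cell_id]) == p.label else "false"].append(
            p.confidence
        )
    per_class: dict[str, dict] = {}
    for cls, g in groups.items():
        t, f = np.asarray(g["true"]), np.asarray(g["false"])
        p_value = None
        if len(t) >= 2 and len(f) >= 2:
            p_value = float(ranksums(t, f).pvalue)
        per_class[cls] = {
            "n_true": len(t),
            "n_false": len(f),
            "true_stats": boxplot_stats(t) if len(t) else None,
            "false_stats": boxplot_stats(f) if len(f) else None,
            "p_value": p_value,
            "significant": False,
        }
    tested = [c for c in per_class if per_class[c]["p_value"] is not None]
    if tested:
        pvals = np.asarray([per_class[c]["p_value"] for c in tested])
        if bh_correct:
            order = np.argsort(pvals)
            m = len(pvals)
            adj = np.empty(m)
            running = 1.0
            for rank_pos in range(m - 1, -1, -1):
                i = order[rank_pos]
                running = min(running, pvals[i] * m / (rank_pos + 1))
                adj[i] = running
            pvals = adj
        for c, pv in zip(tested, pvals):
            per_class[c]["significant"] = bool(pv < alpha)
    return CalibrationReport(per_class=per_class, alpha=alpha)
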