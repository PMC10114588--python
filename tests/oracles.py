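"""Brute-force reference implementations used only as test oracles.

Everything here is written naively (per-cell loops, scipy.stats.spearmanr,
direct counting) and independently of the package's vectorized code paths, so
agreement between the two is meaningful.
"""

import numpy as np
from scipy.stats import spearmanr


def brute_force_singler(
    ref_values, ref_labels, query_row, margin=0.05, genes_per_type=50,
    quantile=0.8,
):
    """Naive per-cell iterative Spearman elimination.

    Shares only the documented conventions with the package implementation:
    gene score = own-type median minus max other-type median (ties by column
    index), per-type aggregation at the given quantile, one round drops the
    lowest-scoring type (score ties: lexicographically last name) plus every
    type more than ``margin`` below the top, keeping at least the top two.
    Returns (label, elimination_history).
    """
    ref_labels = np.asarray(ref_labels, dtype=object)
    surviving = sorted(set(map(str, ref_labels)))
    history = []
    while True:
        # gene selection among surviving types, naive
        medians = {}
        for t in surviving:
            medians[t] = np.median(ref_values[ref_labels == t], axis=0)
        genes = set()
        for t in sorted(surviving):
            scores = []
            for g in range(ref_values.shape[1]):
                others = max(medians[u][g] for u in surviving if u != t)
                scores.append(medians[t][g] - others)
            ranked = sorted(
                range(len(scores)), key=lambda g: (-scores[g], g)
            )
            genes.update(ranked[:genes_per_type])
        genes = sorted(genes)

        # per-type aggregated Spearman correlation, naive
        agg = {}
        for t in surviving:
            cors = []
            for row in ref_values[ref_labels == t]:
                rho = spearmanr(query_row[genes], row[genes]).statistic
                cors.append(0.0 if np.isnan(rho) else rho)
            agg[t] = float(np.percentile(cors, quantile * 100))
        history.append(dict(agg))

        if len(surviving) == 2:
            a, b = sorted(surviving)
            return (a if agg[a] >= agg[b] else b), history

        top = max(agg.values())
        low_score = min(agg.values())
        lowest = max(t for t in surviving if agg[t] == low_score)
        removed = {lowest} | {t for t in surviving if agg[t] < top - margin}
        survivors = [t for t in surviving if t not in removed]
        if len(survivors) < 2:
            ranked = sorted(surviving, key=lambda t: (-agg[t], t))
            survivors = sorted(ranked[:2])
        surviving = sorted(survivors)


def brute_force_metrics(true_labels, pred_labels, unassigned="UNASSIGNED"):
    """Direct per-class recall/precision/F1 by counting, no matrix algebra."""
    out = {}
    for t in sorted(set(true_labels)):
        tp = sum(
            1 for y, p in zip(true_labels, pred_labels) if y == t and p == t
        )
        n_true = sum(1 for y in true_labels if y == t)
        n_pred = sum(1 for p in pred_labels if p == t)
        recall = tp / n_true if n_true else 0.0
        precision = tp / n_pred if n_pred else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        out[t] = {"accuracy": recall, "precision": precision, "f1": f1}
    return out


def brute_force_boxplot(values):
    """Percentiles via sorting + linear interpolation, whiskers by scan."""
    v = sorted(float(x) for x in values)
    n = len(v)

    def pct(q):
        if n == 1:
            return v[0]
        h = q / 100 * (n - 1)
        lo = int(np.floor(h))
        hi = int(np.ceil(h))
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    q1, med, q3 = pct(25), pct(50), pct(75)
    iqr = q3 - q1
    lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = [x for x in v if lo_f <= x <= hi_f]
    outliers = [x for x in v if x < lo_f or x > hi_f]
    return {
        "q1": q1,
        "median": med,
        "q3": q3,
        "whisker_low": min(inside),
        "whisker_high": max(inside),
        "outliers": outliers,
    }
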