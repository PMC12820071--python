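"""Evaluation metrics for rare-outcome prediction.

AUPRC is computed as the precision-recall step integral,
sum_k (R_k - R_{k-1}) * P_k over distinct score thresholds in
descending order — the natural summary for imbalanced case/control
prediction.  Paired model comparisons use the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["auprc", "compare_auprc"]


def auprc(y_true, scores) -> float:
    """Area under the precision-recall curve (step integral).

    Tied scores are grouped into a single threshold.  Constant scores
    yield a single all-positive threshold, so the AUPRC equals the
    prevalence (the random-classifier baseline) by convention.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("AUPRC needs both classes present")
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    # threshold boundaries: last index of each tied block
    boundary = np.flatnonzero(np.diff(s_sorted) != 0.0)
    idx = np.append(boundary, len(y) - 1)
    tp = np.cumsum(y_sorted)[idx]
    npred = idx + 1.0
    precision = tp / npred
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - prev_recall) * precision).sum())


def compare_auprc(auprc_a, auprc_b, zero_method: str = "wilcox") -> dict:
    """Paired comparison of per-iteration AUPRC arrays.

    Wilcoxon signed-rank on the differences: exact null distribution for
    up to 25 informative pairs, normal approximation with continuity
    correction otherwise.  Zero differences are dropped by default
    (``zero_method='pratt'`` keeps them); all-zero differences give
    p = 1 by convention.
    """
    a = np.asarray(auprc_a, dtype=float)
    b = np.asarray(auprc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-d arrays")
    if len(a) < 5:
        raise ValueError("need at least 5 paired iterations")
    d = a - b
    informative = int((d != 0).sum())
    if informative == 0:
        stat, p = 0.0, 1.0
    else:
        method = "exact" if informative <= 25 else "approx"
        res = stats.wilcoxon(d, zero_method=zero_method, method=method,
                             correction=(method == "approx"))
        stat, p = float(res.statistic), float(res.pvalue)
    return {"n": len(a), "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "mean_difference": float(d.mean()), "statistic": stat,
            "p_value": p}
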