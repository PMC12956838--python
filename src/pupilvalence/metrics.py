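"""Classification metrics: the six standard measures plus the P4 composite.

P4 is the harmonic mean of precision, recall, specificity, and negative
predictive value — a conservative single-number summary that penalizes
weakness in any quadrant of the confusion matrix.  Undefined ratios (zero
denominators) are reported as 0.0 with a flag instead of raising, so
degenerate cross-validation folds remain averageable.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .types import MetricSet

__all__ = ["compute_metrics", "p4_score", "mean_roc", "confusion_counts"]

POSITIVE_CLASS = "positive"


def confusion_counts(y_true, y_pred, positive_class=POSITIVE_CLASS):
    yt = np.asarray(y_true) == positive_class
    yp = np.asarray(y_pred) == positive_class
    tp = int(np.sum(yt & yp))
    fp = int(np.sum(~yt & yp))
    tn = int(np.sum(~yt & ~yp))
    fn = int(np.sum(yt & ~yp))
    return tp, fp, tn, fn


def _ratio(num: int, den: int, name: str, flags: set) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def p4_score(tp: int, fp: int, tn: int, fn: int) -> float:
    """Harmonic mean of precision, recall, specificity and NPV.

    Returns 0.0 if any component is undefined (zero denominator) or zero;
    equivalently 4·tp·tn / (4·tp·tn + (tp + tn)·(fp + fn)) when defined.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    components = []
    for num, den in ((tp, tp + fp), (tp, tp + fn), (tn, tn + fp), (tn, tn + fn)):
        if den == 0 or num == 0:
            return 0.0
        components.append(num / den)
    return float(4.0 / sum(1.0 / c for c in components))


def _auc(y_true_bin: np.ndarray, scores, flags: set) -> float:
    if scores is None or len(np.unique(y_true_bin)) < 2:
        flags.add("auc")
        return 0.0
    # rank statistic with 0.5 credit for ties (Mann-Whitney / trapezoid ROC)
    return float(roc_auc_score(y_true_bin, np.asarray(scores, dtype=float)))


def compute_metrics(
    y_true, y_pred, scores=None, positive_class: str = POSITIVE_CLASS
) -> MetricSet:
    """All seven metrics from labels, predictions and continuous scores.

    ``positive_class`` is the positive-valence label throughout the
    pipeline.  AUC uses the rank statistic of the scores (ties get half
    credit); folds whose test set contains a single class get flagged
    zero-valued AUC rather than an exception.
    """
    if len(np.asarray(y_true)) == 0:
        raise ValueError("need at least one sample")
    tp, fp, tn, fn = confusion_counts(y_true, y_pred, positive_class)
    flags: set[str] = set()
    precision = _ratio(tp, tp + fp, "precision", flags)
    recall = _ratio(tp, tp + fn, "recall", flags)
    specificity = _ratio(tn, tn + fp, "specificity", flags)
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    if precision + recall == 0:
        flags.add("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    yt = (np.asarray(y_true) == positive_class).astype(int)
    auc = _auc(yt, scores, flags)
    p4 = p4_score(tp, fp, tn, fn)
    if p4 == 0.0:
        flags.add("p4")
    return MetricSet(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        auc=auc,
        p4=p4,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        flags=frozenset(flags),
    )


def mean_roc(fold_pairs, n_points: int = 101):
    """Vertically averaged ROC curve across folds.

    ``fold_pairs`` is a list of (binary labels, scores) per fold.  Each
    fold's ROC is computed from score thresholds, the TPR is interpolated
    at ``n_points`` evenly spaced FPR values, and curves are averaged
    point-wise with endpoints pinned at (0, 0) and (1, 1).

    Returns (fpr grid, mean tpr, per-fold AUCs, mean AUC, sd AUC).
    """
    fpr_grid = np.linspace(0.0, 1.0, n_points)
    tprs, aucs = [], []
    for y_true, scores in fold_pairs:
        yt = np.asarray(y_true)
        sc = np.asarray(scores, dtype=float)
        if len(np.unique(yt)) < 2:
            continue
        fpr, tpr, _ = roc_curve(yt, sc)
        interp = np.interp(fpr_grid, fpr, tpr)
        interp[0] = 0.0
        tprs.append(interp)
        aucs.append(float(roc_auc_score(yt, sc)))
    if not tprs:
        raise ValueError("no fold with both classes present")
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[-1] = 1.0
    aucs = np.asarray(aucs)
    sd = float(aucs.std(ddof=1)) if aucs.size > 1 else 0.0
    return fpr_grid, mean_tpr, aucs, float(aucs.mean()), sd
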