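"""Evaluation metrics: mean balanced accuracy, the full classification
metric suite, the coefficient of determination, and two-set variation
partitioning.

All classification metrics are computed from the one-vs-rest confusion
counts of each class; "mean" rows are unweighted macro-averages.  The
coefficient of determination R^2 = 1 - SSE/SST (SST around the mean of the
*observed* values) is used as the environmental-influence measure: 0 is
the no-influence baseline of any learner that can always predict the mean,
negative values are reported as-is.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _confusion(truth, predicted, classes=None):
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have the same length")
    if classes is None:
        classes = np.unique(truth)
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(truth, predicted):
        cm[idx[t], idx.get(p, -1)] += 1 if p in idx else 0
    return cm, list(classes)


def balanced_accuracy_per_class(truth, predicted, classes=None) -> pd.Series:
    """Per-class one-vs-rest balanced accuracy 0.5*(TP/P + TN/N)."""
    cm, classes = _confusion(truth, predicted, classes)
    total = cm.sum()
    out = {}
    for i, c in enumerate(classes):
        p = cm[i].sum()
        n = total - p
        if p == 0:
            raise ValueError(f"class {c!r} absent from the truth labels")
        tp = cm[i, i]
        tn = total - p - cm[:, i].sum() + tp
        out[c] = 0.5 * (tp / p + (tn / n if n > 0 else np.nan))
    return pd.Series(out)


def mean_balanced_accuracy(truth, predicted, classes=None) -> float:
    """Macro-average of per-class balanced accuracies, in [0, 1]."""
    return float(balanced_accuracy_per_class(truth, predicted, classes).mean())


def _ratio(num, den):
    return num / den if den > 0 else np.nan


def metric_suite(truth, predicted, classes=None) -> pd.DataFrame:
    """Accuracy, kappa, multiclass Matthews correlation, and per-class plus
    macro-mean balanced accuracy, true skill statistic, F1, precision,
    recall, negative predictive value and true negative rate.

    Returns a frame indexed by metric name with one column per class plus
    ``mean`` and ``overall``; cells that a zero denominator leaves
    undefined are NaN.
    """
    cm, classes = _confusion(truth, predicted, classes)
    total = cm.sum()
    acc = np.trace(cm) / total

    # Cohen's kappa
    pe = np.sum(cm.sum(axis=0) * cm.sum(axis=1)) / total**2
    kappa = (acc - pe) / (1 - pe) if pe < 1 else np.nan

    # generalized (Gorodkin) Matthews correlation
    t_k = cm.sum(axis=1).astype(float)
    p_k = cm.sum(axis=0).astype(float)
    c_ = float(np.trace(cm))
    s = float(total)
    num = c_ * s - np.dot(t_k, p_k)
    den = np.sqrt(s**2 - np.dot(p_k, p_k)) * np.sqrt(s**2 - np.dot(t_k, t_k))
    mcc = num / den if den > 0 else np.nan

    per = {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        recall = _ratio(tp, tp + fn)
        tnr = _ratio(tn, tn + fp)
        precision = _ratio(tp, tp + fp)
        npv = _ratio(tn, tn + fn)
        f1 = (_ratio(2 * precision * recall, precision + recall)
              if np.isfinite(precision) and np.isfinite(recall) else np.nan)
        per[c] = {
            "balanced_accuracy": 0.5 * (recall + tnr),
            "true_skill_statistic": recall + tnr - 1.0,
            "f1": f1,
            "precision": precision,
            "recall": recall,
            "negative_predictive_value": npv,
            "true_negative_rate": tnr,
        }
    frame = pd.DataFrame(per)
    frame["mean"] = frame.mean(axis=1)
    frame["overall"] = np.nan
    for name, value in (("accuracy", acc), ("kappa", kappa),
                        ("matthews_correlation", mcc)):
        frame.loc[name] = np.nan
        frame.loc[name, "overall"] = value
    order = ["accuracy", "kappa", "matthews_correlation", "balanced_accuracy",
             "true_skill_statistic", "f1", "precision", "recall",
             "negative_predictive_value", "true_negative_rate"]
    return frame.loc[order]


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SSE/SST; may be negative, <= 1."""
    y = np.asarray(observed, float)
    f = np.asarray(predicted, float)
    if y.shape != f.shape or y.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    return float(1.0 - np.sum((y - f) ** 2) / sst)


def partition_variation(r2_acc: float, r2_gps: float, r2_combined: float) -> dict:
    """Two-set variation partitioning of explained variance.

    shared = R2_ACC + R2_GPS - R2_combined, and each family's independent
    component is the combined R2 minus the *other* family's R2; the three
    components sum to R2_combined exactly.  Negative components are
    reported as-is.
    """
    shared = r2_acc + r2_gps - r2_combined
    return {
        "r2_acc": r2_acc,
        "r2_gps": r2_gps,
        "r2_combined": r2_combined,
        "shared": shared,
        "independent_acc": r2_combined - r2_gps,
        "independent_gps": r2_combined - r2_acc,
    }
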