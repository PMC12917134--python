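"""Evaluation metrics and bootstrap inference.

Regression: coefficient of determination R^2 = 1 - sum (c_i - chat_i)^2 /
sum (c_i - cbar)^2 (so the train-mean predictor has expected R^2 = 0 and a
random-draw predictor -1), Spearman rho with average-rank ties, and mean
absolute error.  Classification: ROC curve with trapezoidal AUC and the
step-wise average-precision PR-AUC.  Percentile bootstrap confidence
intervals and a paired bootstrap superiority test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

__all__ = [
    "MetricSet", "r_squared", "spearman_rho", "mean_absolute_error",
    "evaluate_predictions", "roc_auc", "pr_auc", "roc_curve_points",
    "pr_curve_points", "bootstrap_metric_ci", "bootstrap_superiority_test",
]


@dataclass
class MetricSet:
    r_squared: float
    spearman_rho: float
    mae: float
    n: int
    valid: bool = True
    ci: dict | None = None  # metric name -> (lower, upper, level)


def r_squared(truth, pred) -> float:
    c = np.asarray(truth, dtype=float)
    chat = np.asarray(pred, dtype=float)
    ss_res = np.sum((c - chat) ** 2)
    ss_tot = np.sum((c - c.mean()) ** 2)
    if ss_tot == 0:
        return np.nan
    return float(1.0 - ss_res / ss_tot)


def spearman_rho(truth, pred) -> float:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input -> nan, by contract
        rho = spearmanr(truth, pred).statistic
    return float(rho)


def mean_absolute_error(truth, pred) -> float:
    return float(np.mean(np.abs(np.asarray(truth, float)
                                - np.asarray(pred, float))))


def evaluate_predictions(truth, pred) -> MetricSet:
    """R^2, Spearman rho and MAE for one set of predictions.

    Requires >= 2 predictions; constant truth makes R^2 (and rho) undefined
    and is reported through ``valid=False`` rather than a silent NaN pass.
    """
    c = np.asarray(truth, dtype=float)
    chat = np.asarray(pred, dtype=float)
    if len(c) < 2 or len(c) != len(chat):
        raise ValueError("need >= 2 paired predictions")
    if np.ptp(c) == 0:
        return MetricSet(np.nan, np.nan, mean_absolute_error(c, chat),
                         n=len(c), valid=False)
    return MetricSet(r_squared(c, chat), spearman_rho(c, chat),
                     mean_absolute_error(c, chat), n=len(c))


# ---------------------------------------------------------------------------
# Classification curves
# ---------------------------------------------------------------------------

def roc_curve_points(scores, labels):
    from sklearn.metrics import roc_curve
    fpr, tpr, thr = roc_curve(labels, scores)
    return fpr, tpr, thr


def roc_auc(scores, labels) -> float:
    from sklearn.metrics import roc_auc_score
    return float(roc_auc_score(labels, scores))


def pr_curve_points(scores, labels):
    from sklearn.metrics import precision_recall_curve
    prec, rec, thr = precision_recall_curve(labels, scores)
    return prec, rec, thr


def pr_auc(scores, labels) -> float:
    """Average precision (step-wise estimator, not interpolated)."""
    from sklearn.metrics import average_precision_score
    return float(average_precision_score(labels, scores))


# ---------------------------------------------------------------------------
# Bootstrap inference
# ---------------------------------------------------------------------------

def bootstrap_metric_ci(truth, pred, metric_fn, n_boot: int = 1000,
                        level: float = 0.95, seed: int = 0,
                        max_redraws: int = 100):
    """Two-sided percentile bootstrap CI over participant-level resamples.

    Degenerate resamples (constant truth, where R^2-type metrics are
    undefined) are redrawn, counted, and capped at ``max_redraws``.
    """
    c = np.asarray(truth, dtype=float)
    chat = np.asarray(pred, dtype=float)
    if len(c) < 10:
        raise ValueError("need >= 10 predictions for a bootstrap CI")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, len(c), len(c))
            if np.ptp(c[idx]) > 0 or redraws >= max_redraws:
                break
            redraws += 1
        stats[b] = metric_fn(c[idx], chat[idx])
    alpha = (1.0 - level) / 2
    lower, upper = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lower), float(upper), level


def bootstrap_superiority_test(truth, pred_a, pred_b, metric_fn=r_squared,
                               n_boot: int = 1000, seed: int = 0,
                               frac_required: float = 0.95):
    """Paired bootstrap test of metric(A) > metric(B).

    Resamples participants with replacement, computes
    ``metric(A) - metric(B)`` per resample, and declares the improvement
    significant when at least ``frac_required`` of the differences are
    strictly positive.  Returns (fraction positive, significant flag).
    """
    c = np.asarray(truth, dtype=float)
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if not (len(c) == len(a) == len(b)):
        raise ValueError("superiority test requires paired predictions on "
                         "identical participants")
    rng = np.random.default_rng(seed)
    positive = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(c), len(c))
        if np.ptp(c[idx]) == 0:
            continue
        diff = metric_fn(c[idx], a[idx]) - metric_fn(c[idx], b[idx])
        if diff > 0:
            positive += 1
    frac = positive / n_boot
    return frac, frac >= frac_required
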