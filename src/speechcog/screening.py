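"""Normative screening for cognitive low performers.

Linear norms of each composite score are estimated on the full cohort,
controlling for age, gender, education and country; participants whose
standardized residual falls below -1.96 in a domain are labelled low
performers for that domain.  A speech-feature SVM then ranks participants,
evaluated with ROC and precision-recall curves plus bootstrap CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composites import _demographic_design
from .metrics import (bootstrap_metric_ci, pr_auc, pr_curve_points, roc_auc,
                      roc_curve_points)

__all__ = [
    "NormativeModel", "ScreenResult",
    "fit_normative_model", "label_low_performers",
    "fit_predict_classifier", "classification_curves",
]


@dataclass
class NormativeModel:
    coefficients: pd.DataFrame   # predictors x domains
    residual_sd: pd.Series       # per domain
    z_scores: pd.DataFrame       # participants x domains
    predictor_names: list[str]


def fit_normative_model(composites: pd.DataFrame,
                        demographics: pd.DataFrame) -> NormativeModel:
    """OLS norms per domain on age/gender/education/country; z = residual /
    residual SD.  Raises on a singular design with a collinearity report."""
    if demographics.isna().any().any():
        raise ValueError("demographics must be complete")
    X = _demographic_design(demographics)
    names = ["intercept", "age", "gender", "education", "country"][:X.shape[1]]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        sds = X.std(axis=0)
        bad = [names[i] for i in range(X.shape[1]) if i > 0 and sds[i] < 1e-12]
        raise ValueError(f"singular normative design (rank {rank} < "
                         f"{X.shape[1]}); suspect collinear/constant "
                         f"predictors: {bad}")
    coefs = {}
    zs = {}
    sds = {}
    for dom in composites.columns:
        y = composites[dom].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = resid.std(ddof=X.shape[1])
        if sd <= 0:
            raise ValueError(f"zero residual SD for domain {dom!r}")
        coefs[dom] = beta
        sds[dom] = sd
        zs[dom] = resid / sd
    return NormativeModel(
        coefficients=pd.DataFrame(coefs, index=names),
        residual_sd=pd.Series(sds),
        z_scores=pd.DataFrame(zs, index=composites.index),
        predictor_names=names,
    )


def label_low_performers(z: pd.Series | np.ndarray,
                         threshold: float = -1.96):
    """Binary labels: 1 iff z < threshold.  Pure threshold function."""
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise ValueError("z-scores must be finite")
    labels = (z_arr < threshold).astype(int)
    if isinstance(z, pd.Series):
        return pd.Series(labels, index=z.index)
    return labels


def fit_predict_classifier(config, X_train: pd.DataFrame, y_train,
                           X_test: pd.DataFrame) -> np.ndarray:
    """SVM (RBF kernel, same regularization discipline as the regression
    setup) decision scores for the test rows.  Raises when a training fold
    contains a single class."""
    y = np.asarray(y_train, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"single-class training fold (class {classes[0]}, "
                         f"n={counts[0]}); cannot fit a classifier")
    Xtr = np.asarray(X_train, dtype=float)
    Xte = np.asarray(X_test, dtype=float)
    if np.isnan(Xtr).any() or np.isnan(Xte).any():
        raise ValueError("feature matrices contain NaN; preprocess first")
    if getattr(config, "kind", "svm") == "random_forest":
        from sklearn.ensemble import RandomForestClassifier
        model = RandomForestClassifier(
            n_estimators=getattr(config, "n_estimators", 100),
            random_state=getattr(config, "seed", 0))
        model.fit(Xtr, y)
        return model.predict_proba(Xte)[:, 1]
    from sklearn.svm import SVC
    model = SVC(kernel=getattr(config, "kernel", "rbf"),
                C=getattr(config, "C", 0.5))
    model.fit(Xtr, y)
    return model.decision_function(Xte)


@dataclass
class ScreenResult:
    roc_auc: float
    pr_auc: float
    prevalence: float
    n: int
    roc_curve: tuple = field(repr=False, default=())
    pr_curve: tuple = field(repr=False, default=())
    roc_auc_ci: tuple | None = None
    pr_auc_ci: tuple | None = None


def classification_curves(scores, labels, n_boot: int = 1000,
                          seed: int = 0, level: float = 0.95
                          ) -> ScreenResult:
    """ROC (trapezoidal AUC) and PR (average-precision AUC) evaluation with
    percentile-bootstrap CIs.  Raises on one-class input."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    roc = roc_auc(scores, labels)
    pr = pr_auc(scores, labels)
    roc_ci = pr_ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        roc_stats, pr_stats = [], []
        draws = 0
        while len(roc_stats) < n_boot and draws < 10 * n_boot:
            draws += 1
            idx = rng.integers(0, len(labels), len(labels))
            if len(np.unique(labels[idx])) < 2:
                continue  # degenerate resample redrawn
            roc_stats.append(roc_auc(scores[idx], labels[idx]))
            pr_stats.append(pr_auc(scores[idx], labels[idx]))
        alpha = (1 - level) / 2
        roc_ci = tuple(np.percentile(roc_stats,
                                     [100 * alpha, 100 * (1 - alpha)]))
        pr_ci = tuple(np.percentile(pr_stats,
                                    [100 * alpha, 100 * (1 - alpha)]))
    return ScreenResult(
        roc_auc=roc, pr_auc=pr,
        prevalence=float(labels.mean()), n=len(labels),
        roc_curve=roc_curve_points(scores, labels),
        pr_curve=pr_curve_points(scores, labels),
        roc_auc_ci=roc_ci, pr_auc_ci=pr_ci,
    )
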