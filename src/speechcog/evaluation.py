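"""The prediction harness: splits, cross-validation, leakage-safe feature
preprocessing, regressors with dummy baselines, and subgroup checks.

Design: an 80/20 development/holdout split stratified on age, gender,
country, education and the binned mean composite score; stratified 10-fold
cross-validation on the development set with results pooled over the union
of fold test sets; all feature statistics (outlier caps, imputation,
standardization) fitted on training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import MetricSet, evaluate_predictions

__all__ = [
    "SplitPlan", "ModelConfig", "FoldPreprocessor",
    "make_strata", "make_holdout_split", "make_cv_folds",
    "preprocess_fold_features", "fit_predict", "cross_validate_predictions",
    "subgroup_metrics",
]

STRATIFICATION_VARS = ("age", "gender", "country", "education")


@dataclass
class SplitPlan:
    dev_ids: list
    holdout_ids: list
    excluded_ids: list
    strata: dict  # id -> stratum label


@dataclass
class ModelConfig:
    kind: str = "svr"  # svr | random_forest | dummy_mean | dummy_random
    kernel: str = "rbf"
    C: float = 0.5
    epsilon: float = 0.1
    n_estimators: int = 100
    folds: int = 10
    bootstrap_n: int = 1000
    confidence: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.kind not in ("svr", "random_forest", "dummy_mean",
                             "dummy_random"):
            raise ValueError(f"unknown model kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

def _bin_continuous(x: pd.Series, n_bins: int = 3) -> pd.Series:
    """Quantile bins (tertiles by default) as integer codes."""
    try:
        return pd.qcut(x, n_bins, labels=False, duplicates="drop")
    except ValueError:
        return pd.Series(np.zeros(len(x), dtype=int), index=x.index)


def make_strata(demographics: pd.DataFrame,
                composite_mean: pd.Series | None = None,
                min_stratum: int = 5) -> tuple[pd.Series, pd.Index]:
    """Stratum label per participant and the ids excluded for missing
    stratification data.

    Label = age tertile x gender x country x education x mean-composite
    tertile; strata smaller than ``min_stratum`` are merged into a pooled
    stratum.
    """
    need = [c for c in STRATIFICATION_VARS if c in demographics.columns]
    mask = demographics[need].notna().all(axis=1)
    if composite_mean is not None:
        composite_mean = composite_mean.reindex(demographics.index)
        mask &= composite_mean.notna()
    excluded = demographics.index[~mask]
    demo = demographics.loc[mask]
    parts = [_bin_continuous(demo["age"]).astype(str)]
    for c in ("gender", "country", "education"):
        if c in demo.columns:
            parts.append(demo[c].astype(str))
    if composite_mean is not None:
        parts.append(_bin_continuous(composite_mean.loc[mask]).astype(str))
    label = parts[0]
    for p in parts[1:]:
        label = label + "|" + p
    counts = label.value_counts()
    small = set(counts.index[counts < min_stratum])
    label = label.where(~label.isin(small), other="__pooled__")
    return label, excluded


def make_holdout_split(demographics: pd.DataFrame,
                       composite_mean: pd.Series | None = None,
                       frac: float = 0.8, seed: int = 0,
                       min_stratum: int = 5) -> SplitPlan:
    """Stratified development/holdout split.

    Participants missing any stratification variable are excluded and
    listed.  Development-set sizes are apportioned per stratum by largest
    remainder, which makes the global development count exactly
    ``round(frac * n)`` (985 retained participants at frac 0.8 -> 788/197).
    Deterministic given ``seed``.
    """
    label, excluded = make_strata(demographics, composite_mean, min_stratum)
    rng = np.random.default_rng(seed)
    n = len(label)
    target_dev = int(round(frac * n))
    groups = {k: list(v) for k, v in label.groupby(label).groups.items()}
    keys = sorted(groups)
    quotas = {k: frac * len(groups[k]) for k in keys}
    base = {k: int(np.floor(quotas[k])) for k in keys}
    leftover = target_dev - sum(base.values())
    by_remainder = sorted(keys, key=lambda k: (-(quotas[k] - base[k]),
                                               -len(groups[k]), k))
    for k in by_remainder[:leftover]:
        base[k] += 1
    dev_ids, holdout_ids = [], []
    for k in keys:
        ids = list(groups[k])
        rng.shuffle(ids)
        dev_ids.extend(ids[:base[k]])
        holdout_ids.extend(ids[base[k]:])
    return SplitPlan(dev_ids=sorted(dev_ids, key=str),
                     holdout_ids=sorted(holdout_ids, key=str),
                     excluded_ids=list(excluded),
                     strata=label.to_dict())


def make_cv_folds(dev_ids: list, strata: dict, k: int = 10,
                  seed: int = 0) -> dict:
    """Stratified k-fold assignment: id -> fold index in [0, k).

    Participants are shuffled within stratum, strata concatenated in
    shuffled order, and the resulting list dealt round-robin, so global
    fold sizes differ by at most 1 and each stratum is spread across folds.
    """
    if k > len(dev_ids):
        raise ValueError("more folds than development participants")
    rng = np.random.default_rng(seed)
    by_stratum: dict[str, list] = {}
    for pid in dev_ids:
        by_stratum.setdefault(str(strata.get(pid, "__pooled__")),
                              []).append(pid)
    ordered: list = []
    stratum_keys = sorted(by_stratum)
    rng.shuffle(stratum_keys)
    for key in stratum_keys:
        ids = sorted(by_stratum[key], key=str)
        rng.shuffle(ids)
        ordered.extend(ids)
    offset = int(rng.integers(0, k))
    return {pid: (i + offset) % k for i, pid in enumerate(ordered)}


# ---------------------------------------------------------------------------
# Leakage-safe feature preprocessing
# ---------------------------------------------------------------------------

class FoldPreprocessor:
    """Per-fold feature transform fitted on training rows only.

    fit: (1) train mean/SD per feature; train cells with |z| > z_cap set
    missing; constant features dropped with a warning; (2) round-robin
    imputer fitted on the masked training matrix; (3) standardization
    statistics taken from the imputed training matrix.

    transform: mask |z| > z_cap against *train* statistics, impute with the
    fitted imputer, standardize with train statistics.  No statistic of the
    apply-set ever enters the transform.
    """

    def __init__(self, z_cap: float = 4.0, seed: int = 0):
        self.z_cap = z_cap
        self.seed = seed
        self.columns_: list[str] | None = None

    def fit(self, train: pd.DataFrame) -> "FoldPreprocessor":
        sd0 = train.std(ddof=0)
        keep = sd0.index[sd0 > 1e-12]
        dropped = [c for c in train.columns if c not in set(keep)]
        if dropped:
            warnings.warn(f"constant features dropped: {dropped}")
        train = train[keep]
        self.columns_ = list(keep)
        self.raw_mean_ = train.mean()
        self.raw_sd_ = train.std(ddof=0)
        masked = self._mask(train)
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer
        from sklearn.linear_model import BayesianRidge
        self.imputer_ = IterativeImputer(
            estimator=BayesianRidge(), max_iter=10, imputation_order="roman",
            initial_strategy="mean", sample_posterior=False,
            random_state=self.seed, keep_empty_features=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filled = self.imputer_.fit_transform(masked.to_numpy(float))
        self.out_mean_ = filled.mean(axis=0)
        self.out_sd_ = filled.std(axis=0, ddof=0)
        self.out_sd_[self.out_sd_ <= 1e-12] = 1.0
        return self

    def _mask(self, df: pd.DataFrame) -> pd.DataFrame:
        z = (df - self.raw_mean_) / self.raw_sd_
        return df.mask(z.abs() > self.z_cap)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise RuntimeError("preprocessor is not fitted")
        df = df[self.columns_]
        masked = self._mask(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filled = self.imputer_.transform(masked.to_numpy(float))
        out = (filled - self.out_mean_) / self.out_sd_
        return pd.DataFrame(out, index=df.index, columns=self.columns_)


def preprocess_fold_features(train: pd.DataFrame, apply_to: pd.DataFrame,
                             z_cap: float = 4.0, seed: int = 0):
    """Fit the leakage-safe transform on ``train`` and apply it to both
    matrices.  Returns (train_transformed, apply_transformed, transform)."""
    if list(train.columns) != list(apply_to.columns):
        raise ValueError("train and apply matrices must share feature "
                         "columns")
    prep = FoldPreprocessor(z_cap=z_cap, seed=seed).fit(train)
    return prep.transform(train), prep.transform(apply_to), prep


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def fit_predict(config: ModelConfig, X_train: pd.DataFrame, y_train,
                X_test: pd.DataFrame):
    """Train the configured model and predict the test rows.

    ``dummy_mean`` returns the training-target mean everywhere;
    ``dummy_random`` samples uniformly with replacement from the training
    targets, independently per test row (seeded).  Returns (predictions,
    fitted model or None).
    """
    Xtr = np.asarray(X_train, dtype=float)
    Xte = np.asarray(X_test, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if np.isnan(Xtr).any() or np.isnan(Xte).any():
        raise ValueError("feature matrices contain NaN; preprocess first")
    if config.kind == "dummy_mean":
        return np.full(len(Xte), y.mean()), None
    if config.kind == "dummy_random":
        rng = np.random.default_rng(config.seed)
        return y[rng.integers(0, len(y), len(Xte))], None
    if config.kind == "svr":
        from sklearn.svm import SVR
        model = SVR(kernel=config.kernel, C=config.C, epsilon=config.epsilon)
    else:
        from sklearn.ensemble import RandomForestRegressor
        model = RandomForestRegressor(n_estimators=config.n_estimators,
                                      random_state=config.seed)
    model.fit(Xtr, y)
    return model.predict(Xte), model


def cross_validate_predictions(X: pd.DataFrame, y: pd.Series, folds: dict,
                               config: ModelConfig,
                               preprocess: bool = True) -> pd.DataFrame:
    """Pooled cross-validation predictions.

    For each fold, features are preprocessed with statistics from the
    training folds only, the model refitted, and the held-out fold
    predicted.  Returns a frame (id, truth, pred, fold) over the union of
    fold test sets; every participant is predicted exactly once, by a model
    that never saw them.
    """
    ids = [i for i in X.index if i in folds]
    X = X.loc[ids]
    y = y.loc[ids]
    fold_of = pd.Series({i: folds[i] for i in ids})
    rows = []
    for f in sorted(fold_of.unique()):
        test_ids = fold_of.index[fold_of == f]
        train_ids = fold_of.index[fold_of != f]
        Xtr, Xte = X.loc[train_ids], X.loc[test_ids]
        if preprocess:
            Xtr, Xte, _ = preprocess_fold_features(Xtr, Xte,
                                                   seed=config.seed)
        pred, _ = fit_predict(config, Xtr, y.loc[train_ids], Xte)
        for pid, p in zip(test_ids, pred):
            rows.append({"id": pid, "truth": float(y.loc[pid]),
                         "pred": float(p), "fold": int(f)})
    return pd.DataFrame(rows).set_index("id")


def subgroup_metrics(truth: pd.Series, pred: pd.Series,
                     groups: pd.Series, low_n: int = 20
                     ) -> dict[str, MetricSet]:
    """Metrics within each subgroup (age bins, gender, country, education).
    Groups smaller than ``low_n`` are flagged via ``MetricSet.valid`` only
    when degenerate; consumers should inspect ``n``."""
    if not truth.index.equals(pred.index):
        raise ValueError("truth and pred must be aligned")
    groups = groups.reindex(truth.index)
    if groups.isna().any():
        raise ValueError("missing group labels")
    out: dict[str, MetricSet] = {}
    for g, idx in truth.groupby(groups).groups.items():
        ms = evaluate_predictions(truth.loc[idx], pred.loc[idx])
        out[str(g)] = ms
    return out
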