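"""Predict the composite cognitive scores from speech features.

The main harness: stratified 80/20 development/holdout split, pooled
10-fold cross-validation with leakage-safe preprocessing, SVR (RBF,
C=0.5) per feature set and domain, dummy baselines, bootstrap CIs, a
superiority test of all features vs demographics, and Shapley feature
importances for the language model.  Reads the feature tables written by
02 and the composites written by 03."""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import (BOOTSTRAP_N, FOLDS, RESULTS, SEED, TABLES,  # noqa: E402
                    ensure_dirs, study_cohort)

from speechcog import metrics as mx  # noqa: E402
from speechcog.evaluation import (FoldPreprocessor, ModelConfig,  # noqa: E402
                                  cross_validate_predictions, fit_predict,
                                  make_cv_folds, make_holdout_split)
from speechcog.shapley import mean_abs_importance, shapley_attributions  # noqa: E402


def load_inputs():
    feats = {p.stem: pd.read_csv(p, index_col=0)
             for p in (RESULTS / "features").glob("*.csv")}
    composites = pd.read_csv(RESULTS / "composites.csv", index_col=0)
    return feats, composites


def main():
    ensure_dirs()
    feats, composites = load_inputs()
    cohort = study_cohort()
    plan = make_holdout_split(cohort.demographics, composites.mean(axis=1),
                              seed=SEED)
    folds = make_cv_folds(plan.dev_ids, plan.strata, k=FOLDS, seed=SEED)

    def usable(df):
        return df[[c for c in df.columns if df[c].notna().mean() > 0.5]]

    sets = {"demographic": feats["demographic"]}
    if "acoustic" in feats:
        sets["acoustic+demographic"] = pd.concat(
            [feats["acoustic"], feats["demographic"]], axis=1)
    sets["linguistic+demographic"] = pd.concat(
        [feats["linguistic"], feats["demographic"]], axis=1)
    if "acoustic" in feats:
        sets["linguistic+acoustic+demographic"] = pd.concat(
            [feats["linguistic"], feats["acoustic"], feats["demographic"]],
            axis=1)
    sets = {k: usable(v) for k, v in sets.items()}

    rows = []
    cv_store = {}
    for set_name, X in sets.items():
        for domain in composites.columns:
            y = composites[domain]
            cfg = ModelConfig(kind="svr", folds=FOLDS, seed=SEED)
            cv = cross_validate_predictions(X.loc[plan.dev_ids],
                                            y.loc[plan.dev_ids], folds, cfg)
            cv_store[(set_name, domain)] = cv
            ms = mx.evaluate_predictions(cv["truth"], cv["pred"])
            lo, hi, _ = mx.bootstrap_metric_ci(cv["truth"], cv["pred"],
                                               mx.r_squared,
                                               n_boot=BOOTSTRAP_N, seed=SEED)
            rows.append({"feature_set": set_name, "domain": domain,
                         "cv_r2": ms.r_squared, "cv_r2_lo": lo,
                         "cv_r2_hi": hi, "cv_spearman": ms.spearman_rho,
                         "cv_mae": ms.mae})
    for domain in composites.columns:
        y = composites[domain]
        for kind in ("dummy_mean", "dummy_random"):
            cfg = ModelConfig(kind=kind, folds=FOLDS, seed=SEED)
            cv = cross_validate_predictions(
                sets["demographic"].loc[plan.dev_ids], y.loc[plan.dev_ids],
                folds, cfg, preprocess=False)
            ms = mx.evaluate_predictions(cv["truth"], cv["pred"])
            rows.append({"feature_set": kind, "domain": domain,
                         "cv_r2": ms.r_squared, "cv_mae": ms.mae})
    table = pd.DataFrame(rows)
    table.round(4).to_csv(TABLES / "regression_summary.csv", index=False)
    print(table.pivot_table(index="feature_set", columns="domain",
                            values="cv_r2").round(3))

    # superiority: all features vs demographics, per domain
    full_name = list(sets)[-1]
    sup_rows = []
    for domain in composites.columns:
        a = cv_store[(full_name, domain)].sort_index()
        b = cv_store[("demographic", domain)].sort_index()
        frac, sig = mx.bootstrap_superiority_test(
            a["truth"], a["pred"], b["pred"], n_boot=BOOTSTRAP_N, seed=SEED)
        sup_rows.append({"domain": domain, "frac_positive": frac,
                         "significant": sig})
    sup = pd.DataFrame(sup_rows)
    sup.to_csv(TABLES / "superiority_tests.csv", index=False)
    print("\nSpeech features vs demographics (paired bootstrap):")
    print(sup)

    # Shapley importances for the language model
    X = sets[full_name]
    y = composites["language"]
    prep = FoldPreprocessor(seed=SEED).fit(X.loc[plan.dev_ids])
    Xt = prep.transform(X.loc[plan.dev_ids])
    _, model = fit_predict(ModelConfig(kind="svr", seed=SEED), Xt,
                           y.loc[plan.dev_ids], Xt)
    rng = np.random.default_rng(SEED)
    bg = Xt.to_numpy()[rng.choice(len(Xt), 40, replace=False)]
    inst = Xt.to_numpy()[rng.choice(len(Xt), 40, replace=False)]
    phi, _ = shapley_attributions(model, bg, inst, n_perm=60, seed=SEED)
    imp = pd.Series(mean_abs_importance(phi), index=Xt.columns)
    imp.sort_values(ascending=False).round(4).to_csv(
        TABLES / "shap_importance_language.csv",
        header=["mean_abs_shap"])
    print("\nTop 10 features for the language model (mean |SHAP|):")
    print(imp.sort_values(ascending=False).head(10).round(3))


if __name__ == "__main__":
    main()
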