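"""Detect cognitive low performers from speech features.

Labels participants with z < -1.96 against demographic-adjusted norms
(fitted on the full cohort) and trains the speech-feature SVM in the same
cross-validation discipline as the regression harness, reporting ROC-AUC
and PR-AUC with bootstrap CIs.

At ~2.5% prevalence the 300-participant study cohort leaves too few
positives for 10-fold CV, so this driver uses a dedicated larger cohort
(n=1200, transcripts only) with the same generative settings; true domain
scores stand in for the CFA composites to keep the stage self-contained.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import BOOTSTRAP_N, FOLDS, SEED, TABLES, ensure_dirs  # noqa: E402

from speechcog.cohort import CohortConfig, generate_cohort  # noqa: E402
from speechcog.evaluation import (ModelConfig, make_cv_folds,  # noqa: E402
                                  make_holdout_split,
                                  preprocess_fold_features)
from speechcog.pipeline import extract_cohort_features  # noqa: E402
from speechcog.screening import (classification_curves,  # noqa: E402
                                 fit_normative_model, fit_predict_classifier,
                                 label_low_performers)

N_SCREEN = 1200


def main():
    ensure_dirs()
    cfg = CohortConfig(n_participants=N_SCREEN, audio_duration_s=5.0,
                       missing_rate=0.0, outlier_rate=0.0, seed=SEED + 1)
    cohort = generate_cohort(cfg)
    composites = cohort.latent_domains  # ground-truth domain scores
    feats = extract_cohort_features(cohort, include_audio=False)
    X = pd.concat([feats["linguistic"], feats["demographic"]], axis=1)
    X = X[[c for c in X.columns if X[c].notna().mean() > 0.5]]

    norm = fit_normative_model(composites,
                               cohort.demographics.drop(columns=["ses"]))
    plan = make_holdout_split(cohort.demographics, composites.mean(axis=1),
                              seed=SEED)
    folds = make_cv_folds(plan.dev_ids, plan.strata, k=FOLDS, seed=SEED)
    fold_of = pd.Series(folds)

    rows = []
    for domain in composites.columns:
        labels = label_low_performers(norm.z_scores[domain])
        dev_labels = labels.loc[plan.dev_ids]
        if dev_labels.sum() < 2 * FOLDS:
            print(f"{domain}: only {int(dev_labels.sum())} low performers "
                  "on the development set; skipped")
            continue
        scores = pd.Series(index=dev_labels.index, dtype=float)
        for f in sorted(set(folds.values())):
            te = fold_of.index[fold_of == f]
            trn = fold_of.index[fold_of != f]
            Xtr, Xte, _ = preprocess_fold_features(X.loc[trn], X.loc[te],
                                                   seed=SEED)
            scores.loc[te] = fit_predict_classifier(
                ModelConfig(seed=SEED), Xtr, dev_labels.loc[trn], Xte)
        res = classification_curves(scores.to_numpy(),
                                    dev_labels.to_numpy(),
                                    n_boot=BOOTSTRAP_N, seed=SEED)
        rows.append({"domain": domain, "n": res.n,
                     "prevalence": res.prevalence,
                     "roc_auc": res.roc_auc, "pr_auc": res.pr_auc,
                     "roc_auc_lo": res.roc_auc_ci[0],
                     "roc_auc_hi": res.roc_auc_ci[1],
                     "pr_auc_lo": res.pr_auc_ci[0],
                     "pr_auc_hi": res.pr_auc_ci[1]})
    table = pd.DataFrame(rows)
    table.round(4).to_csv(TABLES / "screening_summary.csv", index=False)
    print(table.round(3))


if __name__ == "__main__":
    main()
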