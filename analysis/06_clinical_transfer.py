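"""Apply the frozen pipelines to synthetic clinical cohorts.

Trains the per-domain SVR pipelines on the development set, freezes them,
and applies them — without any refitting — to synthetic patient/control
cohorts whose latent cognitive domains are shifted down by delta in
{0, 0.5, 1, 2}.  Reports the patient-control group separation (t-test,
Cohen's d) per domain and delta; d should be ~0 at delta=0 and grow with
the planted impairment."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, SEED, TABLES, ensure_dirs, study_cohort  # noqa: E402

from speechcog.evaluation import (FoldPreprocessor, ModelConfig,  # noqa: E402
                                  fit_predict, make_holdout_split)
from speechcog.pipeline import make_clinical_feature_table  # noqa: E402
from speechcog.transfer import (apply_pretrained, freeze_pipeline,  # noqa: E402
                                group_difference)

DELTAS = (0.0, 0.5, 1.0, 2.0)
N_PER_GROUP = 78  # patients / matched controls


def main():
    ensure_dirs()
    cohort = study_cohort()
    composites = pd.read_csv(RESULTS / "composites.csv", index_col=0)
    feats = {p.stem: pd.read_csv(p, index_col=0)
             for p in (RESULTS / "features").glob("*.csv")}
    X = pd.concat(list(feats.values()), axis=1)
    X = X[[c for c in X.columns if X[c].notna().mean() > 0.5]]
    include_audio = "acoustic" in feats

    plan = make_holdout_split(cohort.demographics, composites.mean(axis=1),
                              seed=SEED)
    prep = FoldPreprocessor(seed=SEED).fit(X.loc[plan.dev_ids])
    Xt = prep.transform(X.loc[plan.dev_ids])
    models = {}
    for domain in composites.columns:
        _, m = fit_predict(ModelConfig(kind="svr", seed=SEED), Xt,
                           composites[domain].loc[plan.dev_ids], Xt)
        models[domain] = m
    pipe = freeze_pipeline(prep, models, list(Xt.columns))

    rows = []
    for delta in DELTAS:
        ext, is_patient = make_clinical_feature_table(
            delta, N_PER_GROUP, include_audio=include_audio,
            audio_duration_s=cohort.config.audio_duration_s,
            seed=SEED + 17)
        ext = ext[[c for c in pipe.feature_names]]
        preds = apply_pretrained(pipe, ext)
        for domain in preds.columns:
            gc = group_difference(preds[domain], is_patient)
            rows.append({"delta": delta, "domain": domain,
                         "cohens_d": gc.cohens_d, "t_stat": gc.t_stat,
                         "p_value": gc.p_value})
    table = pd.DataFrame(rows)
    table.round(4).to_csv(TABLES / "transfer_summary.csv", index=False)
    print(table.pivot_table(index="delta", columns="domain",
                            values="cohens_d").round(3))


if __name__ == "__main__":
    main()
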