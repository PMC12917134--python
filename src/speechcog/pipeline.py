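"""End-to-end study orchestration.

``run_study`` executes the full experimental design on a (synthetic)
cohort: feature extraction, composite scoring, stratified development /
holdout split, pooled 10-fold cross-validation for every feature-set x
domain combination with dummy baselines, holdout evaluation, normative
low-performer screening, and optional clinical transfer.  Every run writes
its resolved configuration, metrics and per-participant predictions to the
run directory, and is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import acoustic as ac
from . import composites as comp
from . import evaluation as ev
from . import linguistic as lng
from . import metrics as mx
from . import screening as scr
from . import transfer as tr
from .cohort import CohortConfig, SyntheticCohort, generate_cohort

__all__ = ["StudyConfig", "run_study", "demographic_features",
           "extract_cohort_features", "compute_composites",
           "make_clinical_feature_table"]


@dataclass
class StudyConfig:
    output_dir: str = "results/run"
    n_participants: int = 300
    include_audio: bool = False
    audio_duration_s: float = 30.0
    folds: int = 10
    holdout_frac: float = 0.8
    bootstrap_n: int = 200
    speech_effect_size: float = 0.5
    audio_effect_size: float = 0.5
    domains: tuple[str, ...] = comp.DOMAINS
    transfer_deltas: tuple[float, ...] = ()
    transfer_n_per_group: int = 60
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=list)


def demographic_features(demographics: pd.DataFrame) -> pd.DataFrame:
    """Numeric demographic design: age, female, high education, UK."""
    return pd.DataFrame({
        "age": demographics["age"].astype(float),
        "gender_female": (demographics["gender"] == "female").astype(float),
        "education_high": (demographics["education"] == "high").astype(float),
        "country_uk": (demographics["country"] == "UK").astype(float),
    }, index=demographics.index)


def extract_cohort_features(cohort: SyntheticCohort,
                            include_audio: bool = False
                            ) -> dict[str, pd.DataFrame]:
    """Linguistic (and optionally acoustic) feature tables per participant."""
    ling_rows = {}
    for pid in cohort.ids:
        fv = lng.extract_linguistic_features(cohort.transcripts[pid].text,
                                             cohort.norm_lexicon)
        ling_rows[pid] = fv.to_dict()
    out = {"linguistic": pd.DataFrame.from_dict(ling_rows, orient="index"),
           "demographic": demographic_features(cohort.demographics)}
    if include_audio:
        ac_rows = {}
        for pid in cohort.ids:
            w = cohort.waveform(pid)
            fv = ac.extract_all_acoustic(w, cohort.transcripts[pid].text)
            ac_rows[pid] = fv.to_dict()
        out["acoustic"] = pd.DataFrame.from_dict(ac_rows, orient="index")
    return out


def compute_composites(cohort: SyntheticCohort,
                       seed: int = 0) -> tuple[pd.DataFrame, comp.FactorModelFit]:
    """Outlier flagging -> round-robin imputation -> CFA -> standardized
    composite scores."""
    flagged, _report = comp.flag_outliers_by_demographic_regression(
        cohort.test_scores, cohort.demographics.drop(columns=["ses"],
                                                     errors="ignore"))
    complete = comp.impute_round_robin(flagged, seed=seed)
    fit = comp.fit_factor_model(complete)
    scores = comp.standardize_columns(fit.factor_scores)
    return scores, fit


def _feature_sets(features: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    sets = {"demographic": features["demographic"]}
    if "acoustic" in features:
        sets["acoustic+demographic"] = pd.concat(
            [features["acoustic"], features["demographic"]], axis=1)
    sets["linguistic+demographic"] = pd.concat(
        [features["linguistic"], features["demographic"]], axis=1)
    if "acoustic" in features:
        sets["linguistic+acoustic+demographic"] = pd.concat(
            [features["linguistic"], features["acoustic"],
             features["demographic"]], axis=1)
    return sets


def _clean_features(df: pd.DataFrame) -> pd.DataFrame:
    """Drop all-invalid columns; remaining NaNs are left for the fold
    preprocessor's imputation stage."""
    keep = [c for c in df.columns if df[c].notna().mean() > 0.5]
    return df[keep]


def run_study(config: StudyConfig) -> Path:
    """Execute the full study; returns the run directory."""
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    cohort_cfg = CohortConfig(
        n_participants=config.n_participants,
        speech_effect_size=config.speech_effect_size,
        audio_effect_size=config.audio_effect_size,
        audio_duration_s=config.audio_duration_s,
        seed=config.seed,
    )
    cohort = generate_cohort(cohort_cfg)
    log.append(f"cohort: n={config.n_participants} seed={config.seed}")

    features = extract_cohort_features(cohort,
                                       include_audio=config.include_audio)
    composites, fit = compute_composites(cohort, seed=config.seed)
    log.append(f"CFA: chi2={fit.chi2:.1f} df={fit.df} cfi={fit.cfi:.3f} "
               f"tli={fit.tli:.3f} rmsea={fit.rmsea:.3f}")

    plan = ev.make_holdout_split(cohort.demographics,
                                 composites.mean(axis=1),
                                 frac=config.holdout_frac, seed=config.seed)
    folds = ev.make_cv_folds(plan.dev_ids, plan.strata, k=config.folds,
                             seed=config.seed)
    log.append(f"split: dev={len(plan.dev_ids)} "
               f"holdout={len(plan.holdout_ids)} "
               f"excluded={len(plan.excluded_ids)}")

    sets = {name: _clean_features(df)
            for name, df in _feature_sets(features).items()}
    results: dict = {"regression": {}, "screening": {}, "transfer": {}}
    pred_frames = []

    for set_name, X in sets.items():
        for domain in config.domains:
            y = composites[domain]
            cfg = ev.ModelConfig(kind="svr", folds=config.folds,
                                 seed=config.seed)
            cv = ev.cross_validate_predictions(
                X.loc[plan.dev_ids], y.loc[plan.dev_ids], folds, cfg)
            ms = mx.evaluate_predictions(cv["truth"], cv["pred"])
            lo, hi, lvl = mx.bootstrap_metric_ci(
                cv["truth"], cv["pred"], mx.r_squared,
                n_boot=config.bootstrap_n, seed=config.seed)
            # holdout: train on full dev
            Xtr, Xte, prep = ev.preprocess_fold_features(
                X.loc[plan.dev_ids], X.loc[plan.holdout_ids],
                seed=config.seed)
            pred_h, _ = ev.fit_predict(cfg, Xtr, y.loc[plan.dev_ids], Xte)
            ms_h = mx.evaluate_predictions(y.loc[plan.holdout_ids], pred_h)
            results["regression"][f"{set_name}|{domain}"] = {
                "cv_r2": ms.r_squared, "cv_r2_ci": [lo, hi],
                "cv_spearman": ms.spearman_rho, "cv_mae": ms.mae,
                "holdout_r2": ms_h.r_squared, "holdout_mae": ms_h.mae,
                "n_dev": ms.n, "n_holdout": ms_h.n,
            }
            cv2 = cv.copy()
            cv2["feature_set"] = set_name
            cv2["domain"] = domain
            pred_frames.append(cv2)

    # dummy baselines (feature-independent; computed once per domain)
    X0 = sets["demographic"]
    for domain in config.domains:
        y = composites[domain]
        for kind in ("dummy_mean", "dummy_random"):
            cfg = ev.ModelConfig(kind=kind, folds=config.folds,
                                 seed=config.seed)
            cv = ev.cross_validate_predictions(
                X0.loc[plan.dev_ids], y.loc[plan.dev_ids], folds, cfg,
                preprocess=False)
            ms = mx.evaluate_predictions(cv["truth"], cv["pred"])
            results["regression"][f"{kind}|{domain}"] = {
                "cv_r2": ms.r_squared, "cv_mae": ms.mae, "n_dev": ms.n}

    # normative screening on the full cohort
    norm = scr.fit_normative_model(
        composites, cohort.demographics.drop(columns=["ses"],
                                             errors="ignore"))
    main_set = sets[list(sets)[-1]]
    for domain in config.domains:
        labels = scr.label_low_performers(norm.z_scores[domain])
        dev_labels = labels.loc[plan.dev_ids]
        fold_of = pd.Series(folds)
        if dev_labels.sum() < 2 * config.folds:
            log.append(f"screening {domain}: too few positives "
                       f"({int(dev_labels.sum())}); skipped")
            continue
        scores = pd.Series(index=dev_labels.index, dtype=float)
        ok = True
        for f in sorted(set(folds.values())):
            te = fold_of.index[fold_of == f]
            trn = fold_of.index[fold_of != f]
            Xtr, Xte, _ = ev.preprocess_fold_features(
                main_set.loc[trn], main_set.loc[te], seed=config.seed)
            try:
                s = scr.fit_predict_classifier(
                    ev.ModelConfig(kind="svr", seed=config.seed),
                    Xtr, dev_labels.loc[trn], Xte)
            except ValueError as err:
                log.append(f"screening {domain} fold {f}: {err}")
                ok = False
                break
            scores.loc[te] = s
        if not ok:
            continue
        res = scr.classification_curves(scores.to_numpy(),
                                        dev_labels.to_numpy(),
                                        n_boot=config.bootstrap_n,
                                        seed=config.seed)
        results["screening"][domain] = {
            "roc_auc": res.roc_auc, "pr_auc": res.pr_auc,
            "prevalence": res.prevalence, "n": res.n,
            "roc_auc_ci": list(res.roc_auc_ci) if res.roc_auc_ci else None,
            "pr_auc_ci": list(res.pr_auc_ci) if res.pr_auc_ci else None,
        }

    # optional clinical transfer
    if config.transfer_deltas:
        frozen = _freeze_main_pipeline(sets, composites, plan, config)
        for delta in config.transfer_deltas:
            ext, is_patient = make_clinical_feature_table(
                delta, config.transfer_n_per_group,
                include_audio=config.include_audio,
                audio_duration_s=config.audio_duration_s,
                seed=config.seed + 17)
            ext = ext[frozen.feature_names]
            preds = tr.apply_pretrained(frozen, ext)
            results["transfer"][str(delta)] = {
                dom: dataclasses.asdict(
                    tr.group_difference(preds[dom], is_patient))
                for dom in preds.columns}

    (run_dir / "config.json").write_text(config.to_json())
    (run_dir / "metrics.json").write_text(
        json.dumps(results, indent=1, sort_keys=True, default=float))
    pd.concat(pred_frames).to_csv(run_dir / "predictions.csv")
    (run_dir / "log.txt").write_text("\n".join(log) + "\n")
    return run_dir


def _freeze_main_pipeline(sets, composites, plan, config) -> tr.FrozenPipeline:
    main_set = sets[list(sets)[-1]]
    X_dev = main_set.loc[plan.dev_ids]
    prep = ev.FoldPreprocessor(seed=config.seed).fit(X_dev)
    Xt = prep.transform(X_dev)
    models = {}
    for domain in config.domains:
        cfg = ev.ModelConfig(kind="svr", seed=config.seed)
        _, model = ev.fit_predict(cfg, Xt, composites[domain].loc[plan.dev_ids],
                                  Xt)
        models[domain] = model
    return tr.freeze_pipeline(prep, models, list(Xt.columns),
                              {"seed": config.seed})


def make_clinical_feature_table(delta: float, n_per_group: int,
                                include_audio: bool = False,
                                audio_duration_s: float = 30.0,
                                seed: int = 0):
    """Synthetic clinical cohort: controls from the standard generative
    process and patients with all four latent domains shifted down by
    ``delta``.  Returns (feature table, is_patient labels)."""
    frames = []
    labels = {}
    for group, shift, s in (("control", 0.0, seed), ("patient", -delta,
                                                     seed + 1)):
        cfg = CohortConfig(
            n_participants=n_per_group,
            latent_shift=(shift,) * 4,
            audio_duration_s=audio_duration_s,
            missing_rate=0.0, outlier_rate=0.0, seed=s)
        cohort = generate_cohort(cfg)
        feats = extract_cohort_features(cohort, include_audio=include_audio)
        table = pd.concat([v for v in feats.values()], axis=1)
        table.index = [f"{group}_{i}" for i in table.index]
        frames.append(table)
        for pid in table.index:
            labels[pid] = group == "patient"
    full = pd.concat(frames)
    return full, pd.Series(labels)
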