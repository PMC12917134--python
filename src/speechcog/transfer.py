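"""Transfer of frozen prediction pipelines to an external cohort.

A :class:`FrozenPipeline` bundles the fitted feature transform and the
fitted regressor per cognitive domain; applying it to external speech
features never refits anything, so no statistic of the external cohort can
leak into the predictions.  Group separation between patients and controls
is quantified with an independent-samples t-test (pooled variance) and
Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import FoldPreprocessor

__all__ = ["FrozenPipeline", "GroupComparison", "freeze_pipeline",
           "apply_pretrained", "group_difference"]


@dataclass
class FrozenPipeline:
    """Fitted transform + fitted regressor per domain, plus the feature
    schema they were trained on."""

    preprocessor: FoldPreprocessor
    models: dict[str, object]          # domain -> fitted regressor
    feature_names: list[str]
    config_fingerprint: dict | None = None


def freeze_pipeline(preprocessor: FoldPreprocessor,
                    models: dict[str, object],
                    feature_names: list[str],
                    config_fingerprint: dict | None = None
                    ) -> FrozenPipeline:
    return FrozenPipeline(preprocessor, dict(models), list(feature_names),
                          config_fingerprint)


def apply_pretrained(pipeline: FrozenPipeline,
                     external: pd.DataFrame) -> pd.DataFrame:
    """Predicted composite scores for an external cohort.

    The external frame must contain every training feature column (missing
    columns raise; extra columns are ignored with a warning).  Rows are
    processed by the frozen transform and models only.
    """
    missing = [c for c in pipeline.feature_names if c not in external.columns]
    if missing:
        raise ValueError(f"external features lack training columns "
                         f"{missing}")
    extra = [c for c in external.columns if c not in pipeline.feature_names]
    if extra:
        warnings.warn(f"ignoring extra feature columns: {extra}")
    X = external[pipeline.feature_names]
    Xt = pipeline.preprocessor.transform(X)
    out = {}
    for domain, model in pipeline.models.items():
        out[domain] = model.predict(np.asarray(Xt, dtype=float))
    return pd.DataFrame(out, index=external.index)


@dataclass
class GroupComparison:
    """d > 0 means the control group scores higher than the patient group
    (control mean minus patient mean over the pooled SD)."""

    mean_control: float
    mean_patient: float
    t_stat: float
    p_value: float
    cohens_d: float
    n_control: int
    n_patient: int


def group_difference(predictions: pd.Series, is_patient: pd.Series
                     ) -> GroupComparison:
    """Two-sample pooled-variance t-test and pooled-SD Cohen's d between
    control (label 0/False) and patient (label 1/True) predictions."""
    is_patient = is_patient.reindex(predictions.index).astype(bool)
    control = predictions[~is_patient].to_numpy(float)
    patient = predictions[is_patient].to_numpy(float)
    if len(control) < 2 or len(patient) < 2:
        raise ValueError("each group needs at least 2 members")
    t, p = stats.ttest_ind(control, patient, equal_var=True)
    n1, n2 = len(control), len(patient)
    pooled = np.sqrt(((n1 - 1) * control.var(ddof=1)
                      + (n2 - 1) * patient.var(ddof=1)) / (n1 + n2 - 2))
    d = (control.mean() - patient.mean()) / pooled if pooled > 0 else 0.0
    return GroupComparison(
        mean_control=float(control.mean()),
        mean_patient=float(patient.mean()),
        t_stat=float(t), p_value=float(p), cohens_d=float(d),
        n_control=n1, n_patient=n2,
    )
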