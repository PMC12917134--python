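"""Shared configuration for the analysis drivers.

One synthetic study cohort (n=300, seed 1) flows through all numbered
scripts; every script regenerates deterministic state from this seed, so
the scripts can be run independently or in sequence.  Outputs land under
results/.
"""

from pathlib import Path

from speechcog.cohort import CohortConfig, generate_cohort

SEED = 1
N_PARTICIPANTS = 300
AUDIO_DURATION_S = 30.0   # scaled-down recordings for the worked analysis
FOLDS = 10
BOOTSTRAP_N = 500

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
TABLES = RESULTS / "tables"


def study_cohort_config() -> CohortConfig:
    return CohortConfig(n_participants=N_PARTICIPANTS,
                        audio_duration_s=AUDIO_DURATION_S, seed=SEED)


def study_cohort():
    return generate_cohort(study_cohort_config())


def ensure_dirs():
    TABLES.mkdir(parents=True, exist_ok=True)
    return RESULTS
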