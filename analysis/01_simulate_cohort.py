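"""Simulate the study cohort and summarise its demographics.

Generates the synthetic cohort (correlated latent cognitive domains with
demographic effects, test scores from the factor structure, transcripts
and waveform plans tied to the latent language/speed scores) and writes
its tables plus a demographic summary."""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, TABLES, ensure_dirs, study_cohort  # noqa: E402


def main():
    ensure_dirs()
    cohort = study_cohort()
    cohort.to_dir(RESULTS / "cohort", write_audio=False)

    demo = cohort.demographics
    summary = pd.DataFrame({
        "value": {
            "n_participants": len(demo),
            "age_mean": demo["age"].mean(),
            "age_sd": demo["age"].std(),
            "frac_female": (demo["gender"] == "female").mean(),
            "frac_uk": (demo["country"] == "UK").mean(),
            "frac_high_education": (demo["education"] == "high").mean(),
            "transcript_words_mean": pd.Series(
                [len(t.text.split()) for t in cohort.transcripts.values()]
            ).mean(),
            "missing_cells": int(cohort.test_scores.isna().sum().sum()),
        }
    })
    summary.to_csv(TABLES / "cohort_summary.csv")
    print("Simulated cohort written to", RESULTS / "cohort")
    print(summary.round(3))


if __name__ == "__main__":
    main()
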