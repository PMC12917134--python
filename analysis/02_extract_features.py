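"""Extract linguistic, acoustic and demographic features for the cohort.

Linguistic features come from the transcripts (POS ratios, lexical
diversity, densities and noun norms, shallow syntax, semantic distances);
acoustic features from the lazily synthesized waveforms (VAD pause/rate
statistics plus the 21-descriptor eGeMAPS-style subset).  Writes one CSV
per feature family."""

import sys
import time
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS, ensure_dirs, study_cohort  # noqa: E402

from speechcog.pipeline import extract_cohort_features  # noqa: E402


def main():
    ensure_dirs()
    cohort = study_cohort()
    t0 = time.time()
    feats = extract_cohort_features(cohort, include_audio=True)
    out = RESULTS / "features"
    out.mkdir(exist_ok=True)
    for name, df in feats.items():
        df.to_csv(out / f"{name}.csv")
        print(f"{name}: {df.shape[1]} features x {df.shape[0]} "
              f"participants -> {out / (name + '.csv')}")
    print(f"extraction took {time.time() - t0:.1f} s")


if __name__ == "__main__":
    main()
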