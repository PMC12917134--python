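import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from speechcog.cohort import CohortConfig, generate_cohort, make_norm_lexicon

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def norm_lexicon():
    return make_norm_lexicon(["boy", "girl", "cookie", "jar", "water",
                              "window", "tree", "house", "dog", "store"],
                             seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with default planted effects, shared across tests."""
    cfg = CohortConfig(n_participants=80, audio_duration_s=10.0, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_scores_cohort():
    """Uncorrupted test scores, no demographic effects: latents have exactly
    the configured correlation structure (used for recovery tests)."""
    eff = pd.DataFrame(0.0, index=["language", "executive_function",
                                   "memory", "speed"],
                       columns=["age", "gender", "education", "country"])
    cfg = CohortConfig(n_participants=5000, missing_rate=0.0,
                       outlier_rate=0.0, demographic_effects=eff,
                       transcript_length=(40, 60), audio_duration_s=5.0,
                       seed=13)
    return generate_cohort(cfg)
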