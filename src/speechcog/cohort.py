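"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes, so every
downstream stage is testable without external data:

* four correlated latent cognitive domains (language, executive function,
  memory, speed) with linear demographic effects;
* test scores generated from a sparse factor-loading structure plus
  Gaussian noise (the battery of 14 sign-harmonised outcome measures);
* transcripts whose lexical diversity and hesitation rate depend
  monotonically on the latent language score (bag-of-template sentences
  over the bundled POS lexicon — POS-taggable and fully controllable, not
  natural language);
* waveform plans with voiced/pause structure and syllable rate depending
  on the latent speed score, rendered lazily as additive-synthesis tones
  plus a low noise floor (16 kHz mono).

Demographic marginals mirror the reference cohort: age ~ N(65.5, 4.8)
truncated at 60, 60/40 female/male, 50/50 UK/USA, 60/40 high/low
education.  All ground truth (latents, planted pause fractions, corruption
masks) is retained for recovery tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._wordlists import DEFAULT_LEXICON_POOLS, SENTENCE_TEMPLATES
from .composites import DEFAULT_TESTS, DOMAINS, FactorModelSpec, default_factor_spec
from .linguistic import NormLexicon, Transcript

__all__ = [
    "CohortConfig", "SyntheticCohort", "WaveformPlan",
    "generate_cohort", "synthesize_transcript", "synthesize_waveform",
    "make_waveform_plan", "make_norm_lexicon", "inject_missing_and_outliers",
    "NORM_RANGES", "default_loadings",
]


def default_loadings(spec: FactorModelSpec | None = None) -> pd.DataFrame:
    """Default loading matrix: 0.8 on each primary loading; the Trail
    Making Test A cross-loading splits as 0.4 executive / 0.5 speed."""
    spec = spec or default_factor_spec()
    lam = pd.DataFrame(0.0, index=spec.tests, columns=list(spec.factors))
    for test, facs in spec.pattern.items():
        if len(facs) == 1:
            lam.loc[test, facs[0]] = 0.8
        else:
            for f, v in zip(facs, (0.4, 0.5)):
                lam.loc[test, f] = v
    return lam


def _default_domain_corr() -> pd.DataFrame:
    """Moderately correlated domains (cognitive domains are not
    independent)."""
    c = np.array([
        [1.0, 0.5, 0.4, 0.4],
        [0.5, 1.0, 0.4, 0.5],
        [0.4, 0.4, 1.0, 0.3],
        [0.4, 0.5, 0.3, 1.0],
    ])
    return pd.DataFrame(c, index=list(DOMAINS), columns=list(DOMAINS))


def _default_demographic_effects() -> pd.DataFrame:
    """Per-domain linear coefficients: age (per year above 65.5), female,
    high education, UK residence."""
    eff = pd.DataFrame(
        {
            "age": [-0.02, -0.03, -0.03, -0.04],
            "gender": [0.05, 0.0, 0.05, 0.0],
            "education": [0.3, 0.3, 0.2, 0.1],
            "country": [0.2, 0.15, 0.1, 0.15],
        },
        index=list(DOMAINS),
    )
    return eff


@dataclass
class CohortConfig:
    n_participants: int = 985
    domain_corr: pd.DataFrame = field(default_factory=_default_domain_corr)
    loading_matrix: pd.DataFrame = field(default_factory=default_loadings)
    demographic_effects: pd.DataFrame = field(
        default_factory=_default_demographic_effects)
    speech_effect_size: float = 0.5
    audio_effect_size: float = 0.5
    noise_sd: float = 0.6
    missing_rate: float = 0.02
    outlier_rate: float = 0.01
    outlier_magnitude_sd: float = 6.0
    transcript_length: tuple[int, int] = (150, 520)
    audio_duration_s: float = 157.0
    sample_rate: int = 16000
    latent_shift: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        c = np.asarray(self.domain_corr, dtype=float)
        if c.shape != (4, 4):
            raise ValueError("domain_corr must be 4x4")
        if not np.allclose(c, c.T):
            raise ValueError("domain_corr must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("domain_corr must have unit diagonal")
        eig = np.linalg.eigvalsh(c)
        if eig.min() <= 1e-10:
            raise ValueError("domain_corr must be positive definite")
        for name in ("speech_effect_size", "audio_effect_size",
                     "missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lam = np.asarray(self.loading_matrix, dtype=float)
        nz = (np.abs(lam) > 0).sum(axis=1)
        if np.any(nz == 0):
            raise ValueError("every test must load on at least one domain")
        if np.any(nz > 2):
            raise ValueError("at most one cross-loading (two domains) per "
                             "test is supported")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")


# ---------------------------------------------------------------------------
# Transcript synthesis
# ---------------------------------------------------------------------------

_CONTENT_TAGS = {"NN", "VB", "VBZ", "VBD", "VBG", "JJ", "RB"}


def synthesize_transcript(latent_language: float,
                          lexicon: dict[str, list[str]] | None = None,
                          length_params: tuple[int, int] = (150, 520),
                          seed: int = 0,
                          participant_id: str = "",
                          task: str = "concatenated") -> Transcript:
    """Template-based transcript whose lexical diversity rises and whose
    hesitation rate falls monotonically with ``latent_language``.

    Generative mapping (documented): content words are Zipf-sampled from
    their POS pool with exponent ``a = max(0.4, 1.3 - 0.3 * latent)`` —
    higher latent flattens the distribution, raising the type-token ratio —
    and an interjection is inserted before a token with probability
    ``clip(0.06 - 0.02 * latent, 0.005, 0.25)``.  Token count (hesitations
    included) is uniform in ``length_params`` and exact.
    """
    pools = lexicon or DEFAULT_LEXICON_POOLS
    if not pools or any(len(v) == 0 for v in pools.values()):
        raise ValueError("lexicon must be non-empty for every POS pool")
    needed = {t for tpl in SENTENCE_TEMPLATES for t in tpl} | {"UH"}
    missing = needed - set(pools)
    if missing:
        raise ValueError(f"lexicon lacks POS classes {missing}")
    lo, hi = length_params
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_params")
    rng = np.random.default_rng(seed)
    n_tokens = int(rng.integers(lo, hi + 1))
    a = max(0.4, 1.3 - 0.3 * float(latent_language))
    p_hes = float(np.clip(0.06 - 0.02 * float(latent_language), 0.005, 0.25))

    def zipf_choice(pool: list[str]) -> str:
        ranks = np.arange(1, len(pool) + 1, dtype=float)
        w = ranks ** (-a)
        return pool[rng.choice(len(pool), p=w / w.sum())]

    sentences: list[list[str]] = []
    total = 0
    while total < n_tokens:
        tpl = SENTENCE_TEMPLATES[rng.integers(0, len(SENTENCE_TEMPLATES))]
        sent: list[str] = []
        for slot in tpl:
            if rng.random() < p_hes:
                sent.append(pools["UH"][rng.integers(0, len(pools["UH"]))])
            pool = pools[slot]
            if slot in _CONTENT_TAGS:
                sent.append(zipf_choice(pool))
            else:
                sent.append(pool[rng.integers(0, len(pool))])
        sentences.append(sent)
        total += len(sent)
    # trim to the exact token count, dropping any empty trailing sentence
    excess = total - n_tokens
    while excess > 0:
        drop = min(excess, len(sentences[-1]))
        sentences[-1] = sentences[-1][:len(sentences[-1]) - drop]
        if not sentences[-1]:
            sentences.pop()
        excess -= drop
    text = ". ".join(" ".join(s) for s in sentences) + "."
    return Transcript(participant_id=participant_id, task=task, text=text)


# ---------------------------------------------------------------------------
# Waveform plans and synthesis
# ---------------------------------------------------------------------------

@dataclass
class WaveformPlan:
    """Ground-truth voiced/pause plan for one recording."""

    voiced_intervals: list[tuple[float, float]]
    duration_s: float
    f0: float = 120.0
    syllable_rate: float = 4.0
    seed: int = 0

    def __post_init__(self):
        prev = 0.0
        for s, e in self.voiced_intervals:
            if s < prev - 1e-9 or e <= s:
                raise ValueError("plan intervals must be sorted, "
                                 "non-overlapping, positive length")
            prev = e
        if self.voiced_intervals and \
                self.voiced_intervals[-1][1] > self.duration_s + 1e-9:
            raise ValueError("plan interval exceeds total duration")

    @property
    def pause_fraction(self) -> float:
        """Planted internal-pause fraction over the trimmed span."""
        iv = self.voiced_intervals
        if not iv:
            return 0.0
        span = iv[-1][1] - iv[0][0]
        voiced = sum(e - s for s, e in iv)
        return (span - voiced) / span if span > 0 else 0.0


def make_waveform_plan(latent_speed: float, duration_s: float = 157.0,
                       seed: int = 0, f0: float | None = None
                       ) -> WaveformPlan:
    """Alternating voiced/pause plan whose pause fraction falls and whose
    syllable rate rises with ``latent_speed``.

    Target pause fraction ``clip(0.30 - 0.06 * latent, 0.05, 0.60)``;
    syllable rate ``clip(4.0 + 0.4 * latent, 2.0, 7.0)`` Hz; voiced burst
    lengths lognormal around 1.8 s.
    """
    rng = np.random.default_rng(seed)
    p = float(np.clip(0.30 - 0.06 * latent_speed, 0.05, 0.60))
    rate = float(np.clip(4.0 + 0.4 * latent_speed, 2.0, 7.0))
    mean_voiced = 1.8
    mean_pause = mean_voiced * p / (1 - p)
    intervals = []
    t = float(rng.uniform(0.2, 0.8))  # leading silence
    while t < duration_s - 0.5:
        v = float(np.clip(rng.lognormal(np.log(mean_voiced), 0.35), 0.4, 8.0))
        end = min(t + v, duration_s - 0.2)
        if end - t > 0.2:
            intervals.append((t, end))
        t = end + float(np.clip(rng.lognormal(np.log(max(mean_pause, 0.05)),
                                              0.35), 0.05, 6.0))
    return WaveformPlan(intervals, duration_s,
                        f0=f0 if f0 else float(rng.uniform(100, 220)),
                        syllable_rate=rate, seed=seed)


def synthesize_waveform(plan: WaveformPlan, sample_rate: int = 16000,
                        seed: int | None = None, amplitude: float = 0.3,
                        noise_amplitude: float = 1e-3):
    """Render a plan as harmonic tone bursts over a low noise floor.

    Voiced intervals carry a three-harmonic tone at the plan's f0,
    amplitude-modulated at the syllable rate (producing loudness peaks);
    pauses contain only the noise floor.  Returns a
    :class:`~speechcog.acoustic.Waveform`.
    """
    from .acoustic import Waveform
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    n = int(round(plan.duration_s * sample_rate))
    x = noise_amplitude * rng.standard_normal(n)
    t = np.arange(n) / sample_rate
    for s, e in plan.voiced_intervals:
        i0, i1 = int(s * sample_rate), min(int(e * sample_rate), n)
        tt = t[i0:i1]
        env = 0.55 + 0.45 * np.sin(2 * np.pi * plan.syllable_rate * tt)
        tone = (np.sin(2 * np.pi * plan.f0 * tt)
                + 0.5 * np.sin(2 * np.pi * 2 * plan.f0 * tt)
                + 0.25 * np.sin(2 * np.pi * 3 * plan.f0 * tt))
        x[i0:i1] += amplitude * env * tone
    return Waveform(x, sample_rate)


# ---------------------------------------------------------------------------
# Norm lexicon
# ---------------------------------------------------------------------------

NORM_RANGES = {
    "frequency": (0.1, 5000.0),
    "aoa": (1.0, 18.0),
    "familiarity": (300.0, 700.0),
    "ambiguity": (1.0, 10.0),
    "concreteness": (1.0, 5.0),
}


def make_norm_lexicon(vocabulary: list[str], seed: int = 0) -> NormLexicon:
    """Assign psycholinguistic norms from documented distributions:
    frequency lognormal(3, 1.5), age of acquisition N(6, 2), familiarity
    N(550, 50), ambiguity lognormal(0.3, 0.4), concreteness N(3.5, 0.8),
    each clipped to ``NORM_RANGES``.  Deterministic per seed."""
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    rng = np.random.default_rng(seed)
    entries = {}
    for word in sorted(set(w.lower() for w in vocabulary)):
        entries[word] = {
            "frequency": float(np.clip(rng.lognormal(3.0, 1.5),
                                       *NORM_RANGES["frequency"])),
            "aoa": float(np.clip(rng.normal(6.0, 2.0), *NORM_RANGES["aoa"])),
            "familiarity": float(np.clip(rng.normal(550.0, 50.0),
                                         *NORM_RANGES["familiarity"])),
            "ambiguity": float(np.clip(rng.lognormal(0.3, 0.4),
                                       *NORM_RANGES["ambiguity"])),
            "concreteness": float(np.clip(rng.normal(3.5, 0.8),
                                          *NORM_RANGES["concreteness"])),
        }
    return NormLexicon(entries)


# ---------------------------------------------------------------------------
# Corruption (missingness and outliers)
# ---------------------------------------------------------------------------

def inject_missing_and_outliers(test_scores: pd.DataFrame,
                                missing_rate: float, outlier_rate: float,
                                outlier_magnitude_sd: float = 6.0,
                                seed: int = 0,
                                demographics: pd.DataFrame | None = None):
    """Corrupt a complete score table with missing cells and planted
    outliers; returns (corrupted table, mask frame with '' / 'missing' /
    'outlier').

    Outliers are placed at least ``outlier_magnitude_sd`` residual SDs from
    the demographic regression line of their column (column mean line when
    no demographics are given), with random sign.
    """
    for name, rate in (("missing_rate", missing_rate),
                       ("outlier_rate", outlier_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = test_scores.copy()
    mask = pd.DataFrame("", index=test_scores.index,
                        columns=test_scores.columns)
    if demographics is not None:
        from .composites import _demographic_design
        X = _demographic_design(demographics)
    else:
        X = np.ones((len(test_scores), 1))
    for col in test_scores.columns:
        y = test_scores[col].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        line = X @ beta
        sd = (y - line).std(ddof=X.shape[1]) or 1.0
        u = rng.random(len(y))
        is_missing = u < missing_rate
        is_outlier = (~is_missing) & (u < missing_rate + outlier_rate)
        for i in np.flatnonzero(is_outlier):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            out.iloc[i, out.columns.get_loc(col)] = (
                line[i] + sign * (outlier_magnitude_sd
                                  + abs(rng.standard_normal())) * sd)
            mask.iloc[i, mask.columns.get_loc(col)] = "outlier"
        for i in np.flatnonzero(is_missing):
            out.iloc[i, out.columns.get_loc(col)] = np.nan
            mask.iloc[i, mask.columns.get_loc(col)] = "missing"
    return out, mask


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: CohortConfig
    demographics: pd.DataFrame
    latent_domains: pd.DataFrame
    test_scores: pd.DataFrame          # possibly corrupted
    clean_test_scores: pd.DataFrame
    corruption_mask: pd.DataFrame
    transcripts: dict[str, Transcript]
    waveform_plans: dict[str, WaveformPlan]
    norm_lexicon: NormLexicon
    truth: dict = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return list(self.demographics.index)

    def waveform(self, participant_id: str):
        """Synthesize the participant's waveform from its stored plan
        (lazy: plans are cheap, samples are not)."""
        return synthesize_waveform(self.waveform_plans[participant_id],
                                   sample_rate=self.config.sample_rate)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for df in (self.demographics, self.latent_domains, self.test_scores):
            h.update(df.round(12).to_csv().encode())
        for pid in self.ids:
            h.update(self.transcripts[pid].text.encode())
            plan = self.waveform_plans[pid]
            h.update(json.dumps([plan.voiced_intervals, plan.duration_s,
                                 plan.f0, plan.syllable_rate]).encode())
        return h.hexdigest()

    def to_dir(self, path, write_audio: bool = False) -> None:
        """Persist as CSV/JSON (+ optional WAV) with a truth.json."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.demographics.to_csv(path / "demographics.csv")
        self.test_scores.to_csv(path / "test_scores.csv")
        recs = [{"id": pid, "task": t.task, "text": t.text}
                for pid, t in self.transcripts.items()]
        (path / "transcripts.json").write_text(json.dumps(recs, indent=1))
        self.norm_lexicon.to_csv(path / "norm_lexicon.csv")
        truth = {
            "latent_domains": self.latent_domains.round(10).to_dict("index"),
            "pause_fractions": {pid: p.pause_fraction
                                for pid, p in self.waveform_plans.items()},
            "seed": self.config.seed,
        }
        (path / "truth.json").write_text(json.dumps(truth, indent=1))
        if write_audio:
            from .acoustic import write_wav
            audio_dir = path / "audio"
            audio_dir.mkdir(exist_ok=True)
            for pid in self.ids:
                write_wav(audio_dir / f"{pid}.wav", self.waveform(pid))


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Deterministic cohort draw under ``config``.

    Latents are multivariate normal with the configured correlation plus
    linear demographic shifts; test scores are loadings @ latents plus
    N(0, noise_sd); transcripts/waveform plans are driven by a mixture
    ``sqrt(e) * latent + sqrt(1-e) * independent noise`` so the stated
    effect-size fractions of latent variance reach the observables.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ids = [f"P{i:04d}" for i in range(n)]

    age = stats.truncnorm.rvs((60 - 65.5) / 4.8, np.inf, loc=65.5, scale=4.8,
                              size=n, random_state=rng)
    gender = np.where(rng.random(n) < 0.6, "female", "male")
    country = np.where(rng.random(n) < 0.5, "UK", "USA")
    education = np.where(rng.random(n) < 0.6, "high", "low")
    ses = np.clip(rng.normal(5.7, 1.6, n), 1, 10)
    demographics = pd.DataFrame(
        {"age": np.round(age, 2), "gender": gender, "country": country,
         "education": education, "ses": np.round(ses, 2)}, index=ids)

    corr = np.asarray(config.domain_corr, dtype=float)
    chol = np.linalg.cholesky(corr)
    latents = rng.standard_normal((n, 4)) @ chol.T
    eff = config.demographic_effects
    shift = np.zeros((n, 4))
    indicators = {
        "age": age - 65.5,
        "gender": (gender == "female").astype(float),
        "education": (education == "high").astype(float),
        "country": (country == "UK").astype(float),
    }
    for j, dom in enumerate(DOMAINS):
        for var, x in indicators.items():
            shift[:, j] += float(eff.loc[dom, var]) * x
    latents = latents + shift + np.asarray(config.latent_shift, dtype=float)
    latent_df = pd.DataFrame(latents, index=ids, columns=list(DOMAINS))

    lam = np.asarray(config.loading_matrix, dtype=float)
    tests = list(config.loading_matrix.index)
    scores = latents @ lam.T + config.noise_sd * rng.standard_normal(
        (n, len(tests)))
    clean_scores = pd.DataFrame(scores, index=ids, columns=tests)

    corrupt_seed = int(rng.integers(0, 2 ** 31))
    if config.missing_rate > 0 or config.outlier_rate > 0:
        corrupted, mask = inject_missing_and_outliers(
            clean_scores, config.missing_rate, config.outlier_rate,
            config.outlier_magnitude_sd, seed=corrupt_seed,
            demographics=demographics)
    else:
        corrupted = clean_scores.copy()
        mask = pd.DataFrame("", index=ids, columns=tests)

    e_speech = config.speech_effect_size
    e_audio = config.audio_effect_size
    lang = latent_df["language"].to_numpy()
    speed = latent_df["speed"].to_numpy()
    speech_driver = (np.sqrt(e_speech) * lang
                     + np.sqrt(1 - e_speech) * rng.standard_normal(n))
    audio_driver = (np.sqrt(e_audio) * speed
                    + np.sqrt(1 - e_audio) * rng.standard_normal(n))

    t_seeds = rng.integers(0, 2 ** 31, n)
    w_seeds = rng.integers(0, 2 ** 31, n)
    transcripts = {}
    plans = {}
    for i, pid in enumerate(ids):
        transcripts[pid] = synthesize_transcript(
            speech_driver[i], length_params=config.transcript_length,
            seed=int(t_seeds[i]), participant_id=pid)
        plans[pid] = make_waveform_plan(
            audio_driver[i], duration_s=config.audio_duration_s,
            seed=int(w_seeds[i]))

    vocab = sorted({w for pool in DEFAULT_LEXICON_POOLS.values()
                    for w in pool})
    lexicon = make_norm_lexicon(vocab, seed=config.seed)

    return SyntheticCohort(
        config=config, demographics=demographics, latent_domains=latent_df,
        test_scores=corrupted, clean_test_scores=clean_scores,
        corruption_mask=mask, transcripts=transcripts, waveform_plans=plans,
        norm_lexicon=lexicon,
        truth={"speech_driver": dict(zip(ids, speech_driver.tolist())),
               "audio_driver": dict(zip(ids, audio_driver.tolist()))},
    )
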