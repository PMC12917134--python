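"""Automated scoring of the standardized language tasks.

Semantic fluency (valid animal names against a dictionary, with greedy
multiword matching), phonemic fluency (distinct words with the target
initial letter, excluding number words and proper nouns), a 20-item
confrontation-naming task, plus transcription quality (word error rate)
and auto-vs-manual agreement (MAE and two-way ICC for absolute agreement).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._wordlists import ANIMALS, NUMBER_WORDS

__all__ = [
    "AnswerKey", "AgreementReport",
    "score_semantic_fluency", "score_phonemic_fluency",
    "score_boston_naming", "word_error_rate", "agreement_stats",
    "default_answer_key",
]


@dataclass
class AnswerKey:
    """Answer keys for the three language tasks."""

    animals: frozenset[str]
    phonemic_letter: str = "f"
    phonemic_exclusions: frozenset[str] = frozenset()
    naming_items: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self):
        if not self.animals:
            raise ValueError("animal key must be non-empty")
        self.phonemic_letter = self.phonemic_letter.lower()


def default_answer_key(n_naming_items: int = 20) -> AnswerKey:
    """Bundled key: animal dictionary, letter-F fluency with number-word
    exclusions, and a synthetic naming key built from common object nouns."""
    objects = ["cup", "jar", "window", "tree", "house", "chair", "table",
               "book", "boat", "kite", "ladder", "spoon", "bottle", "flag",
               "shoe", "hat", "door", "ball", "basket", "towel"]
    items = [frozenset([w]) for w in objects[:n_naming_items]]
    return AnswerKey(animals=frozenset(ANIMALS),
                     phonemic_exclusions=frozenset(NUMBER_WORDS),
                     naming_items=items)


_WORD_RE = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)?")


def _simple_lemma(word: str) -> str:
    """Crude singularisation so 'dogs' matches key entry 'dog'."""
    w = word.lower()
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("es") and len(w) > 4 and w[-3] in "sxzh":
        return w[:-2]
    if w.endswith("s") and not w.endswith("ss") and len(w) > 3:
        return w[:-1]
    return w


def score_semantic_fluency(tokens: list[str], key: AnswerKey) -> int:
    """Number of distinct animal-key entries matched in the token stream.

    Matching is case-insensitive and lemma-based; multiword key entries
    ("polar bear") are matched greedily, longest first, and consume their
    tokens.  Repetitions count once.
    """
    words = [_simple_lemma(t) for t in tokens if t]
    multi = sorted((a.split() for a in key.animals if " " in a),
                   key=len, reverse=True)
    single = {a for a in key.animals if " " not in a}
    matched: set[str] = set()
    i = 0
    while i < len(words):
        hit = False
        for parts in multi:
            if words[i:i + len(parts)] == list(parts):
                matched.add(" ".join(parts))
                i += len(parts)
                hit = True
                break
        if not hit:
            if words[i] in single:
                matched.add(words[i])
            i += 1
    return len(matched)


def score_phonemic_fluency(tokens: list[str], key: AnswerKey) -> int:
    """Number of distinct words starting with the target letter, minus
    exclusions (number words; capitalized tokens are treated as proper nouns
    and excluded).  Morphological variants of an already-counted word count
    once (lemma-level deduplication)."""
    counted: set[str] = set()
    for t in tokens:
        if not t:
            continue
        lw = t.lower()
        if not lw.startswith(key.phonemic_letter):
            continue
        if lw in key.phonemic_exclusions:
            continue
        if t[0].isupper():  # proper-noun rule
            continue
        counted.add(_simple_lemma(lw))
    return len(counted)


def _normalize_response(resp: str) -> str:
    words = [w.lower() for w in _WORD_RE.findall(resp)]
    words = [w for w in words if w not in ("a", "an", "the")]
    return " ".join(words)


def score_boston_naming(responses: list[str], key: AnswerKey) -> int:
    """Number of items whose normalised response (lowercased, articles
    stripped) is in that item's acceptable set."""
    if len(responses) != len(key.naming_items):
        raise ValueError(f"expected {len(key.naming_items)} responses, "
                         f"got {len(responses)}")
    correct = 0
    for resp, acceptable in zip(responses, key.naming_items):
        norm = _normalize_response(resp)
        if norm and norm in {a.lower() for a in acceptable}:
            correct += 1
    return correct


def word_error_rate(reference: list[str], hypothesis: list[str]) -> float:
    """(substitutions + insertions + deletions) / len(reference), via
    minimum edit distance over tokens (case-insensitive)."""
    if not reference:
        raise ValueError("reference must be non-empty")
    ref = [w.lower() for w in reference]
    hyp = [w.lower() for w in hypothesis]
    m, n = len(ref), len(hyp)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if ref[i - 1] == hyp[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[n] / m


@dataclass
class AgreementReport:
    mae: float
    icc: float
    n: int


def agreement_stats(auto_scores, manual_scores) -> AgreementReport:
    """Mean absolute error and ICC(2,1) — two-way random effects, absolute
    agreement, single rater (Shrout & Fleiss) — between automated and manual
    scores."""
    a = np.asarray(auto_scores, dtype=float)
    b = np.asarray(manual_scores, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 paired scores")
    mae = float(np.mean(np.abs(a - b)))
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom) if denom != 0 else 1.0
    return AgreementReport(mae=mae, icc=icc, n=n)
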