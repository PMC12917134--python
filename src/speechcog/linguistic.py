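"""Transcript-derived linguistic features.

Computes the lexical, syntactic and semantic feature set used throughout the
analysis: part-of-speech ratios, lexical diversity (moving-average type-token
ratio, Brunet's index, Honore's statistic, unique words per 50-word sample),
propositional/content density, psycholinguistic noun norms, shallow
constituency statistics, Flesch-Kincaid readability, and TF-IDF-based
between-sentence semantic distances.

Tokenisation and tagging are deliberately hermetic: a bundled Penn-Treebank
lexicon with documented suffix fallbacks, and a deterministic POS-driven chunk
grammar for the constituency counts.  The mapping from PTB tags to the coarse
classes the ratio features name lives in :mod:`speechcog._wordlists`.
"""

from __future__ import annotations

import csv
import itertools
import math
import re
from dataclasses import dataclass, field

import numpy as np

from ._wordlists import (
    COORDINATE_CONJUNCTIONS,
    ENGLISH_DICTIONARY,
    SUBORDINATE_CONJUNCTIONS,
    SYLLABLE_EXCEPTIONS,
    TAG_LEXICON,
    TAG_TO_CLASS,
)
from .features import FeatureVector

__all__ = [
    "Transcript",
    "Token",
    "TokenSequence",
    "NormLexicon",
    "LINGUISTIC_FEATURES",
    "tokenize_and_tag",
    "pos_ratio_features",
    "lexical_diversity_features",
    "density_and_norm_features",
    "syntactic_parse_features",
    "semantic_distance_features",
    "extract_linguistic_features",
    "count_syllables",
]


@dataclass
class Transcript:
    """One participant's transcript for one speech task."""

    participant_id: str
    task: str  # cookie_theft | picnic | journaling | concatenated
    text: str


@dataclass
class Token:
    surface: str
    lemma: str
    tag: str          # Penn Treebank tag
    sent_idx: int

    @property
    def word_class(self) -> str:
        """Coarse class; IN tokens split into prep vs subordinating conj."""
        if self.tag == "IN" and self.lemma in SUBORDINATE_CONJUNCTIONS:
            return "sconj"
        return TAG_TO_CLASS.get(self.tag, "other")


@dataclass
class TokenSequence:
    tokens: list[Token] = field(default_factory=list)
    n_sentences: int = 0

    def __len__(self) -> int:
        return len(self.tokens)

    def surfaces(self, lower: bool = True) -> list[str]:
        return [t.surface.lower() if lower else t.surface for t in self.tokens]

    def sentences(self) -> list[list[Token]]:
        out: list[list[Token]] = [[] for _ in range(self.n_sentences)]
        for t in self.tokens:
            out[t.sent_idx].append(t)
        return out


class NormLexicon:
    """Psycholinguistic word norms: frequency, age of acquisition,
    familiarity, ambiguity, concreteness.  Lookups are case-insensitive."""

    FIELDS = ("frequency", "aoa", "familiarity", "ambiguity", "concreteness")

    def __init__(self, entries: dict[str, dict[str, float]]):
        self._entries = {w.lower(): dict(v) for w, v in entries.items()}
        for w, v in self._entries.items():
            missing = set(self.FIELDS) - set(v)
            if missing:
                raise ValueError(f"norm entry {w!r} missing fields {missing}")

    def __contains__(self, word: str) -> bool:
        return word.lower() in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def get(self, word: str) -> dict[str, float] | None:
        return self._entries.get(word.lower())

    def words(self) -> list[str]:
        return list(self._entries)

    def coverage(self, words: list[str]) -> float:
        if not words:
            return 0.0
        return sum(w.lower() in self._entries for w in words) / len(words)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(("word",) + self.FIELDS)
            for word, v in sorted(self._entries.items()):
                w.writerow([word] + [v[f] for f in self.FIELDS])

    @classmethod
    def from_csv(cls, path) -> "NormLexicon":
        entries: dict[str, dict[str, float]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries[row["word"]] = {f: float(row[f]) for f in cls.FIELDS}
        return cls(entries)


# ---------------------------------------------------------------------------
# Tokenisation and tagging
# ---------------------------------------------------------------------------

_WORD_RE = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)?")
_SENT_SPLIT_RE = re.compile(r"[.!?]+")


def _fallback_tag(word: str) -> str:
    """Suffix-based tag guess for out-of-lexicon words (documented rules)."""
    w = word.lower()
    if w.endswith("ly") and len(w) > 3:
        return "RB"
    if w.endswith("ing") and len(w) > 4:
        return "VBG"
    if w.endswith("ed") and len(w) > 3:
        return "VBD"
    if w.endswith("s") and len(w) > 3:
        stem = w[:-1]
        if TAG_LEXICON.get(stem) == "VB":
            return "VBZ"
        return "NNS"
    return "NN"


def tokenize_and_tag(text: str) -> TokenSequence:
    """Split ``text`` into sentences and word tokens and assign PTB tags.

    Sentences are split on runs of ``.!?``; tokens are alphabetic runs with
    optional internal apostrophe (punctuation is never emitted as a token).
    Tags come from the bundled lexicon; unknown capitalised words that are not
    sentence-initial are tagged ``NNP``, other unknowns by suffix rules.

    Raises ``ValueError`` on empty / whitespace-only input.
    """
    if not text or not text.strip():
        raise ValueError("cannot tokenize empty or whitespace-only text")
    seq = TokenSequence()
    sent_idx = 0
    for raw_sent in _SENT_SPLIT_RE.split(text):
        words = _WORD_RE.findall(raw_sent)
        if not words:
            continue
        for pos, w in enumerate(words):
            lw = w.lower()
            if lw in TAG_LEXICON:
                tag = TAG_LEXICON[lw]
            elif w[0].isupper() and pos > 0:
                tag = "NNP"
            elif re.fullmatch(r"\d+", w):
                tag = "CD"
            else:
                tag = _fallback_tag(w)
            lemma = lw
            if tag == "NNS" and lw.endswith("s"):
                lemma = lw[:-1]
            seq.tokens.append(Token(w, lemma, tag, sent_idx))
        sent_idx += 1
    seq.n_sentences = sent_idx
    if not seq.tokens:
        raise ValueError("text contains no word tokens")
    return seq


# ---------------------------------------------------------------------------
# POS-ratio / lexical features
# ---------------------------------------------------------------------------

def pos_ratio_features(tokens: TokenSequence,
                       dictionary: frozenset[str] = ENGLISH_DICTIONARY,
                       ) -> FeatureVector:
    """Part-of-speech ratio features plus word count / length / dictionary
    coverage.  Denominator for every ``*_ratio`` is the number of word tokens
    (punctuation is excluded at tokenisation; interjections count as words)."""
    fv = FeatureVector()
    n = len(tokens)
    counts: dict[str, int] = {}
    for t in tokens.tokens:
        counts[t.word_class] = counts.get(t.word_class, 0) + 1
    tag_counts: dict[str, int] = {}
    for t in tokens.tokens:
        tag_counts[t.tag] = tag_counts.get(t.tag, 0) + 1

    nouns = counts.get("noun", 0) + counts.get("propn", 0)
    verbs = counts.get("verb", 0)

    fv.set("n_words", n)
    if nouns > 0:
        fv.set("verb_noun_ratio", verbs / nouns)
    else:
        fv.set_invalid("verb_noun_ratio")
    n_sub = sum(1 for t in tokens.tokens if t.word_class == "sconj")
    n_coord = counts.get("cconj", 0)
    if n_coord > 0:
        fv.set("subordinate_coordinate_conjunction_ratio", n_sub / n_coord)
    else:
        fv.set_invalid("subordinate_coordinate_conjunction_ratio")
    fv.set("adverb_ratio", counts.get("adv", 0) / n)
    fv.set("noun_ratio", nouns / n)
    fv.set("verb_ratio", verbs / n)
    pron = counts.get("pron", 0)
    fv.set("pronoun_ratio", pron / n)
    fv.set("personal_pronoun_ratio", tag_counts.get("PRP", 0) / n)
    fv.set("determiner_ratio", counts.get("det", 0) / n)
    n_prep = sum(1 for t in tokens.tokens if t.word_class == "prep")
    fv.set("preposition_ratio", n_prep / n)
    fv.set("verb_present_participle_ratio", tag_counts.get("VBG", 0) / n)
    fv.set("verb_modal_ratio", counts.get("modal", 0) / n)
    fv.set("verb_third_person_singular_ratio", tag_counts.get("VBZ", 0) / n)
    fv.set("interjection_ratio", counts.get("intj", 0) / n)
    fv.set("avg_word_length",
           sum(len(t.surface) for t in tokens.tokens) / n)
    fv.set("words_not_in_dict_ratio",
           sum(1 for t in tokens.tokens
               if t.surface.lower() not in dictionary) / n)
    return fv


def _sliding_windows(items: list, width: int):
    """All contiguous windows of ``width``; the whole list if shorter."""
    if len(items) <= width:
        yield items
        return
    for i in range(len(items) - width + 1):
        yield items[i:i + width]


def lexical_diversity_features(tokens: TokenSequence, window: int = 20,
                               sample_size: int = 50) -> FeatureVector:
    """Lexical diversity and richness.

    * ``moving_average_type_token_ratio``: mean type/token ratio over all
      contiguous windows of ``window`` tokens (the whole text as a single
      window when shorter).
    * ``n_unique_in_50``: mean number of unique tokens over all contiguous
      windows of ``sample_size`` tokens (same short-text rule).
    * ``brunets_index``: W = N^(V^-0.165).
    * ``honores_statistic``: R = 100 ln(N) / (1 - V1/V); flagged invalid when
      every type is a hapax (V1 = V), where R diverges.

    Types are lower-cased surfaces.
    """
    fv = FeatureVector()
    words = tokens.surfaces(lower=True)
    n = len(words)
    ttrs = [len(set(w)) / len(w) for w in _sliding_windows(words, window)]
    fv.set("moving_average_type_token_ratio", float(np.mean(ttrs)))
    uniq = [len(set(w)) for w in _sliding_windows(words, sample_size)]
    fv.set("n_unique_in_50", float(np.mean(uniq)))
    types = set(words)
    v = len(types)
    fv.set("brunets_index", n ** (v ** -0.165))
    from collections import Counter
    freqs = Counter(words)
    v1 = sum(1 for c in freqs.values() if c == 1)
    if v1 == v:
        fv.set_invalid("honores_statistic")
    else:
        fv.set("honores_statistic", 100.0 * math.log(n) / (1.0 - v1 / v))
    return fv


_PROPOSITIONAL_CLASSES = {"verb", "modal", "adj", "adv", "prep", "cconj", "sconj"}
_CONTENT_CLASSES = {"noun", "propn", "verb", "adj", "adv"}

_NORM_FEATURES = {
    "frequency_noun": "frequency",
    "age_of_acquisition_noun": "aoa",
    "familiarity_noun": "familiarity",
    "ambiguity_noun": "ambiguity",
    "noun_concreteness": "concreteness",
}


def density_and_norm_features(tokens: TokenSequence,
                              lexicon: NormLexicon) -> FeatureVector:
    """Propositional/content density and mean psycholinguistic noun norms.

    Propositional density counts verbs (incl. modals), adjectives, adverbs,
    prepositions and conjunctions; content density counts nouns, verbs,
    adjectives and adverbs.  Norm features average the lexicon value over
    noun tokens covered by the lexicon; ``norm_coverage`` reports the covered
    fraction and all five norms are flagged invalid with zero coverage.
    """
    fv = FeatureVector()
    n = len(tokens)
    classes = [t.word_class for t in tokens.tokens]
    fv.set("propositional_density",
           sum(c in _PROPOSITIONAL_CLASSES for c in classes) / n)
    fv.set("content_density",
           sum(c in _CONTENT_CLASSES for c in classes) / n)
    noun_words = [t.surface.lower() for t in tokens.tokens
                  if t.word_class in ("noun", "propn")]
    covered = [w for w in noun_words if w in lexicon]
    fv.set("norm_coverage",
           len(covered) / len(noun_words) if noun_words else 0.0)
    if not covered:
        for name in _NORM_FEATURES:
            fv.set_invalid(name)
        return fv
    for name, fieldname in _NORM_FEATURES.items():
        fv.set(name, float(np.mean([lexicon.get(w)[fieldname]
                                    for w in covered])))
    return fv


# ---------------------------------------------------------------------------
# Shallow constituency features
# ---------------------------------------------------------------------------

_VERB_TAGS = {"VB", "VBD", "VBG", "VBN", "VBP", "VBZ"}
_NOUN_TAGS = {"NN", "NNS", "NNP", "NNPS"}


def count_syllables(word: str) -> int:
    """Dictionary-first syllable count with a vowel-group fallback.

    Fallback: number of maximal ``[aeiouy]+`` groups, minus one for a silent
    final 'e' (not '-le'), with a floor of 1.
    """
    w = word.lower()
    if w in SYLLABLE_EXCEPTIONS:
        return SYLLABLE_EXCEPTIONS[w]
    groups = re.findall(r"[aeiouy]+", w)
    count = len(groups)
    if w.endswith("e") and not w.endswith("le") and count > 1:
        count -= 1
    return max(count, 1)


def _chunk_sentence(sent: list[Token]):
    """Deterministic shallow parse of one tagged sentence.

    Returns (constituents, production_counts, has_vp) where constituents are
    (label, n_words) pairs over NP / VP / PP / INTJ chunks.
    """
    tags = [t.tag for t in sent]
    n = len(sent)
    items: list[tuple[str, int, int, list[str]]] = []  # (kind, start, end, tags)
    i = 0
    while i < n:
        tag = tags[i]
        if tag == "UH":
            items.append(("INTJ", i, i + 1, ["UH"]))
            i += 1
        elif tag == "PRP":
            items.append(("NP", i, i + 1, ["PRP"]))
            i += 1
        elif tag in {"DT", "PRP$", "JJ"} | _NOUN_TAGS:
            j = i
            if tags[j] in ("DT", "PRP$"):
                j += 1
            while j < n and tags[j] == "JJ":
                j += 1
            k = j
            while k < n and tags[k] in _NOUN_TAGS:
                k += 1
            if k > j:
                items.append(("NP", i, k, tags[i:k]))
                i = k
            else:
                i += 1  # bare determiner/adjective: no chunk
        elif tag == "MD" or tag in _VERB_TAGS:
            j = i
            if tags[j] == "MD":
                j += 1
            while j < n and tags[j] in _VERB_TAGS:
                j += 1
            items.append(("VG", i, j, tags[i:j]))
            i = j
        elif tag == "IN":
            items.append(("P", i, i + 1, ["IN"]))
            i += 1
        else:
            i += 1

    constituents: list[tuple[str, int]] = []
    prods = {k: 0 for k in ("NP_to_PRP", "VP_to_VBG", "VP_to_VBG_PP",
                            "VP_to_VBD_NP", "INTJ_to_UH")}
    # PPs: preposition immediately followed by an NP chunk
    pp_starts: dict[int, int] = {}  # P item index -> end token of the PP
    for idx, (kind, s, e, _tg) in enumerate(items):
        if kind == "P" and idx + 1 < len(items):
            nkind, ns, ne, _ = items[idx + 1]
            if nkind == "NP" and ns == e:
                pp_starts[idx] = ne
                constituents.append(("PP", ne - s))
    has_vp = False
    for idx, (kind, s, e, tg) in enumerate(items):
        if kind == "NP":
            constituents.append(("NP", e - s))
            if tg == ["PRP"]:
                prods["NP_to_PRP"] += 1
        elif kind == "INTJ":
            constituents.append(("INTJ", 1))
            prods["INTJ_to_UH"] += 1
        elif kind == "VG":
            has_vp = True
            comp_kind, vp_end = None, e
            if idx + 1 < len(items):
                nkind, ns, ne, _ = items[idx + 1]
                if ns == e:
                    if nkind == "NP":
                        comp_kind, vp_end = "NP", ne
                    elif nkind == "P" and (idx + 1) in pp_starts:
                        comp_kind, vp_end = "PP", pp_starts[idx + 1]
            constituents.append(("VP", vp_end - s))
            if tg == ["VBG"]:
                if comp_kind == "PP":
                    prods["VP_to_VBG_PP"] += 1
                elif comp_kind is None:
                    prods["VP_to_VBG"] += 1
            elif tg and tg[-1] == "VBD" and comp_kind == "NP":
                prods["VP_to_VBD_NP"] += 1
    return constituents, prods, has_vp


def syntactic_parse_features(text: str) -> FeatureVector:
    """Constituency-based counts from the shallow chunk grammar, plus the
    Flesch-Kincaid grade level.

    ``flesch_kincaid = 0.39 * words/sentences + 11.8 * syllables/word - 15.59``
    """
    fv = FeatureVector()
    seq = tokenize_and_tag(text)
    all_cons: list[tuple[str, int]] = []
    prods = {k: 0 for k in ("NP_to_PRP", "ROOT_to_FRAG", "VP_to_VBG",
                            "VP_to_VBG_PP", "VP_to_VBD_NP", "INTJ_to_UH")}
    for sent in seq.sentences():
        cons, p, has_vp = _chunk_sentence(sent)
        all_cons.extend(cons)
        for k, v in p.items():
            prods[k] += v
        if not has_vp:
            prods["ROOT_to_FRAG"] += 1
    for k, v in prods.items():
        fv.set(k, v)
    n_cons = len(all_cons)
    nps = [c for c in all_cons if c[0] == "NP"]
    vps = [c for c in all_cons if c[0] == "VP"]
    fv.set("NP_ratio", len(nps) / n_cons if n_cons else 0.0)
    fv.set("VP_ratio", len(vps) / n_cons if n_cons else 0.0)
    if nps:
        fv.set("avg_n_words_in_NP", float(np.mean([c[1] for c in nps])))
    else:
        fv.set_invalid("avg_n_words_in_NP")
    n_words = len(seq)
    n_sents = seq.n_sentences
    syllables = sum(count_syllables(t.surface) for t in seq.tokens)
    fv.set("flesch_kincaid",
           0.39 * n_words / n_sents + 11.8 * syllables / n_words - 15.59)
    return fv


# ---------------------------------------------------------------------------
# Semantic distance features
# ---------------------------------------------------------------------------

def semantic_distance_features(tokens: TokenSequence) -> FeatureVector:
    """Average TF-IDF cosine distance between sentence pairs and the
    proportion of pairs with distance <= 0.5.

    TF-IDF weighting: raw term counts times smoothed idf
    ``ln((1+n)/(1+df)) + 1`` with L2-normalised sentence vectors (the
    standard sklearn weighting, documented here as the contract).  Requires
    at least two sentences; flagged invalid otherwise.
    """
    fv = FeatureVector()
    sents = [" ".join(t.surface.lower() for t in s) for s in tokens.sentences()]
    sents = [s for s in sents if s]
    if len(sents) < 2:
        fv.set_invalid("avg_distance_between_utterances")
        fv.set_invalid("prop_utterance_dist_below_05")
        return fv
    from sklearn.feature_extraction.text import TfidfVectorizer
    vec = TfidfVectorizer(token_pattern=r"(?u)\b\w+\b", lowercase=True)
    mat = vec.fit_transform(sents).toarray()
    dists = []
    for i, j in itertools.combinations(range(len(sents)), 2):
        dists.append(1.0 - float(mat[i] @ mat[j]))
    fv.set("avg_distance_between_utterances", float(np.mean(dists)))
    fv.set("prop_utterance_dist_below_05",
           float(np.mean([d <= 0.5 for d in dists])))
    return fv


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

#: Fixed output order of the linguistic feature vector.
LINGUISTIC_FEATURES: tuple[str, ...] = (
    "n_words", "verb_noun_ratio", "subordinate_coordinate_conjunction_ratio",
    "adverb_ratio", "noun_ratio", "verb_ratio", "pronoun_ratio",
    "personal_pronoun_ratio", "determiner_ratio", "preposition_ratio",
    "verb_present_participle_ratio", "verb_modal_ratio",
    "verb_third_person_singular_ratio", "interjection_ratio",
    "avg_word_length", "words_not_in_dict_ratio", "brunets_index",
    "honores_statistic", "moving_average_type_token_ratio", "n_unique_in_50",
    "propositional_density", "content_density", "frequency_noun",
    "age_of_acquisition_noun", "familiarity_noun", "ambiguity_noun",
    "noun_concreteness",
    "NP_to_PRP", "ROOT_to_FRAG", "VP_to_VBG", "VP_to_VBG_PP", "VP_to_VBD_NP",
    "INTJ_to_UH", "NP_ratio", "VP_ratio", "avg_n_words_in_NP",
    "flesch_kincaid",
    "avg_distance_between_utterances", "prop_utterance_dist_below_05",
)


def extract_linguistic_features(text: str, lexicon: NormLexicon,
                                window: int = 20,
                                sample_size: int = 50) -> FeatureVector:
    """Full linguistic feature vector in the fixed documented order.

    Sub-extractors report degenerate cases through validity flags, which
    propagate; no silent NaN is ever produced for a valid feature.
    """
    tokens = tokenize_and_tag(text)
    fv = FeatureVector()
    fv.update(pos_ratio_features(tokens))
    fv.update(lexical_diversity_features(tokens, window=window,
                                         sample_size=sample_size))
    fv.update(density_and_norm_features(tokens, lexicon))
    fv.update(syntactic_parse_features(text))
    fv.update(semantic_distance_features(tokens))
    return fv.reorder(list(LINGUISTIC_FEATURES))
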