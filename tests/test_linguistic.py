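"""Linguistic feature extraction: tagger, POS ratios, lexical diversity,
densities and norms, shallow syntax, semantic distances."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speechcog import linguistic as L
from speechcog.cohort import make_norm_lexicon
from speechcog.linguistic import (LINGUISTIC_FEATURES, NormLexicon,
                                  count_syllables, tokenize_and_tag)


# ---------------------------------------------------------------------------
# Tokenisation and tagging
# ---------------------------------------------------------------------------

class TestTokenizer:
    def test_basic_sentence(self):
        seq = tokenize_and_tag("The boy runs.")
        assert [t.surface for t in seq.tokens] == ["The", "boy", "runs"]
        assert all(t.sent_idx == 0 for t in seq.tokens)
        assert seq.n_sentences == 1

    def test_two_sentences(self):
        seq = tokenize_and_tag("The boy runs. The girl sits.")
        assert seq.n_sentences == 2
        assert max(t.sent_idx for t in seq.tokens) == 1

    def test_hesitations_tagged_as_interjections(self):
        seq = tokenize_and_tag("uh the uh cookie")
        assert [t.tag for t in seq.tokens] == ["UH", "DT", "UH", "NN"]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            tokenize_and_tag("   \n ")


# ---------------------------------------------------------------------------
# POS ratios
# ---------------------------------------------------------------------------

class TestPosRatios:
    def test_hand_counted_ratios(self):
        # DET NOUN VERB ADP DET NOUN
        seq = tokenize_and_tag("the boy runs to the store")
        fv = L.pos_ratio_features(seq)
        assert fv["noun_ratio"] == pytest.approx(2 / 6)
        assert fv["verb_ratio"] == pytest.approx(1 / 6)
        assert fv["determiner_ratio"] == pytest.approx(2 / 6)
        assert fv["preposition_ratio"] == pytest.approx(1 / 6)
        assert fv["n_words"] == 6

    def test_all_nouns(self):
        fv = L.pos_ratio_features(tokenize_and_tag("boy girl cookie"))
        assert fv["noun_ratio"] == 1.0

    def test_avg_word_length(self):
        fv = L.pos_ratio_features(tokenize_and_tag("cat cat"))
        assert fv["avg_word_length"] == 3.0

    def test_zero_nouns_flags_verb_noun_ratio(self):
        fv = L.pos_ratio_features(tokenize_and_tag("runs quickly"))
        assert not fv.is_valid("verb_noun_ratio")


# ---------------------------------------------------------------------------
# Lexical diversity
# ---------------------------------------------------------------------------

class TestLexicalDiversity:
    def test_mattr_hand_enumeration(self):
        seq = tokenize_and_tag("aa aa bb bb")
        fv = L.lexical_diversity_features(seq, window=2)
        assert fv["moving_average_type_token_ratio"] == pytest.approx(
            (0.5 + 1.0 + 0.5) / 3)

    def test_identical_tokens_give_unique_count_one(self):
        text = " ".join(["cat"] * 50)
        fv = L.lexical_diversity_features(tokenize_and_tag(text))
        assert fv["n_unique_in_50"] == 1.0

    def test_brunet_formula(self):
        # N=100 tokens, V=20 types (alphabetic words; digits are not tokens)
        words = ["w" + chr(ord("a") + i) for i in range(20)] * 5
        fv = L.lexical_diversity_features(tokenize_and_tag(" ".join(words)))
        assert fv["brunets_index"] == pytest.approx(100 ** (20 ** -0.165),
                                                    rel=1e-9)

    def test_honore_formula(self):
        # N=10, V=5, V1=2: aa x4, bb x3, cc, dd, ee -> hapaxes {cc,dd,ee}?
        words = ["aa"] * 4 + ["bb"] * 3 + ["cc"] * 2 + ["dd"]
        # N=10, V=4, V1=1 -> R = 100 ln10 / (1 - 1/4)
        fv = L.lexical_diversity_features(tokenize_and_tag(" ".join(words)))
        assert fv["honores_statistic"] == pytest.approx(
            100 * math.log(10) / 0.75, rel=1e-9)

    def test_honore_all_hapax_flagged_invalid(self):
        fv = L.lexical_diversity_features(tokenize_and_tag("aa bb cc"))
        assert not fv.is_valid("honores_statistic")

    def test_mattr_is_one_for_all_unique_tokens(self):
        import itertools
        pairs = itertools.product("abcdefgh", repeat=2)
        text = " ".join("".join(p) for _, p in zip(range(60), pairs))
        fv = L.lexical_diversity_features(tokenize_and_tag(text))
        assert fv["moving_average_type_token_ratio"] == 1.0

    @given(st.lists(st.sampled_from(["boy", "girl", "dog", "tree", "house"]),
                    min_size=1, max_size=120),
           st.integers(min_value=2, max_value=25))
    @settings(max_examples=40, deadline=None)
    def test_windowed_statistics_match_brute_force(self, words, window):
        seq = tokenize_and_tag(" ".join(words))
        fv = L.lexical_diversity_features(seq, window=window,
                                          sample_size=window)
        lowered = [w.lower() for w in words]
        if len(lowered) <= window:
            wins = [lowered]
        else:
            wins = [lowered[i:i + window]
                    for i in range(len(lowered) - window + 1)]
        brute_mattr = np.mean([len(set(w)) / len(w) for w in wins])
        brute_uni = np.mean([len(set(w)) for w in wins])
        assert fv["moving_average_type_token_ratio"] == pytest.approx(
            brute_mattr, abs=1e-12)
        assert fv["n_unique_in_50"] == pytest.approx(brute_uni, abs=1e-12)


# ---------------------------------------------------------------------------
# Density and norm features
# ---------------------------------------------------------------------------

class TestDensities:
    def test_hand_counted_densities(self):
        seq = tokenize_and_tag("the boy runs to the store")
        lex = make_norm_lexicon(["boy", "store"], seed=0)
        fv = L.density_and_norm_features(seq, lex)
        assert fv["propositional_density"] == pytest.approx(2 / 6)
        assert fv["content_density"] == pytest.approx(3 / 6)

    def test_constant_lexicon_value_passes_through(self):
        seq = tokenize_and_tag("the boy sees the store")
        lex = NormLexicon({w: {"frequency": 5.0, "aoa": 6.0,
                               "familiarity": 500.0, "ambiguity": 1.0,
                               "concreteness": 4.0}
                           for w in ("boy", "store")})
        fv = L.density_and_norm_features(seq, lex)
        assert fv["frequency_noun"] == 5.0
        assert fv["norm_coverage"] == 1.0

    def test_no_nouns_invalidates_all_norm_features(self):
        seq = tokenize_and_tag("runs quickly")
        lex = make_norm_lexicon(["boy"], seed=0)
        fv = L.density_and_norm_features(seq, lex)
        for name in ("frequency_noun", "age_of_acquisition_noun",
                     "familiarity_noun", "ambiguity_noun",
                     "noun_concreteness"):
            assert not fv.is_valid(name)


# ---------------------------------------------------------------------------
# Shallow syntax
# ---------------------------------------------------------------------------

class TestSyntax:
    def test_flesch_kincaid_hand_value(self):
        fv = L.syntactic_parse_features("The cat sat.")
        assert fv["flesch_kincaid"] == pytest.approx(
            0.39 * 3 + 11.8 * 1 - 15.59, abs=1e-9)

    def test_no_noun_phrases_gives_zero_np_ratio(self):
        fv = L.syntactic_parse_features("runs quickly.")
        assert fv["NP_ratio"] == 0.0

    def test_simple_np_word_count(self):
        fv = L.syntactic_parse_features("the big dog runs.")
        assert fv["avg_n_words_in_NP"] == 3.0

    def test_production_rule_counts_on_fixture(self):
        # "he is running through the garden. uh the boy took the cookie."
        fv = L.syntactic_parse_features(
            "he is running through the garden. uh the boy took the cookie.")
        assert fv["NP_to_PRP"] == 1        # "he"
        assert fv["INTJ_to_UH"] == 1       # "uh"
        assert fv["VP_to_VBD_NP"] == 1     # "took the cookie"
        assert fv["ROOT_to_FRAG"] == 0

    def test_verbless_sentence_counts_as_fragment(self):
        fv = L.syntactic_parse_features("the big garden. the boy runs.")
        assert fv["ROOT_to_FRAG"] == 1

    def test_syllable_counter(self):
        assert count_syllables("cat") == 1
        assert count_syllables("cookie") == 2
        assert count_syllables("banana") == 3
        assert count_syllables("time") == 1  # silent e


# ---------------------------------------------------------------------------
# Semantic distances
# ---------------------------------------------------------------------------

class TestSemanticDistances:
    def test_identical_sentences(self):
        seq = tokenize_and_tag("the boy runs. the boy runs.")
        fv = L.semantic_distance_features(seq)
        assert fv["avg_distance_between_utterances"] == pytest.approx(0.0,
                                                                      abs=1e-9)
        assert fv["prop_utterance_dist_below_05"] == 1.0

    def test_disjoint_vocabulary(self):
        seq = tokenize_and_tag("boy girl water. tree house dog.")
        fv = L.semantic_distance_features(seq)
        assert fv["avg_distance_between_utterances"] == pytest.approx(1.0)
        assert fv["prop_utterance_dist_below_05"] == 0.0

    def test_three_sentences_match_brute_force(self):
        text = "the boy runs. the girl runs. the dog sits."
        seq = tokenize_and_tag(text)
        fv = L.semantic_distance_features(seq)
        # independent brute force with the documented weighting
        sents = [["the", "boy", "runs"], ["the", "girl", "runs"],
                 ["the", "dog", "sits"]]
        vocab = sorted({w for s in sents for w in s})
        n = len(sents)
        df = {w: sum(w in s for s in sents) for w in vocab}
        vecs = []
        for s in sents:
            v = np.array([s.count(w) * (math.log((1 + n) / (1 + df[w])) + 1)
                          for w in vocab])
            vecs.append(v / np.linalg.norm(v))
        dists = [1 - float(vecs[i] @ vecs[j])
                 for i, j in itertools.combinations(range(n), 2)]
        assert fv["avg_distance_between_utterances"] == pytest.approx(
            np.mean(dists), abs=1e-9)

    def test_single_sentence_flagged_invalid(self):
        seq = tokenize_and_tag("the boy runs.")
        fv = L.semantic_distance_features(seq)
        assert not fv.is_valid("avg_distance_between_utterances")


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

class TestExtractAll:
    def test_fixed_order_and_determinism(self, small_cohort):
        text = small_cohort.transcripts[small_cohort.ids[0]].text
        lex = small_cohort.norm_lexicon
        a = L.extract_linguistic_features(text, lex)
        b = L.extract_linguistic_features(text, lex)
        assert a.names == list(LINGUISTIC_FEATURES)
        assert a.values == b.values

    def test_concatenation_adds_word_counts(self, norm_lexicon):
        t1 = "the boy runs to the store."
        t2 = "the girl sits by the window."
        n1 = L.extract_linguistic_features(t1, norm_lexicon)["n_words"]
        n2 = L.extract_linguistic_features(t2, norm_lexicon)["n_words"]
        n12 = L.extract_linguistic_features(t1 + " " + t2,
                                            norm_lexicon)["n_words"]
        assert n12 == n1 + n2

    def test_proportions_stay_in_unit_interval(self, small_cohort):
        lex = small_cohort.norm_lexicon
        ratio_feats = [f for f in LINGUISTIC_FEATURES
                       if f.endswith("_ratio") and f != "verb_noun_ratio"
                       and f != "subordinate_coordinate_conjunction_ratio"]
        for pid in small_cohort.ids[:10]:
            fv = L.extract_linguistic_features(
                small_cohort.transcripts[pid].text, lex)
            for f in ratio_feats:
                assert 0.0 <= fv[f] <= 1.0, f
            assert 0.0 < fv["moving_average_type_token_ratio"] <= 1.0
            assert 1.0 <= fv["n_unique_in_50"] <= 50.0

    def test_trailing_whitespace_and_case_invariance(self, norm_lexicon):
        base = "the boy runs to the store. the girl sits."
        a = L.extract_linguistic_features(base, norm_lexicon)
        b = L.extract_linguistic_features(base + "   \n", norm_lexicon)
        assert a.values == b.values
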