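"""Bundled word lists: POS lexicon, animal dictionary, phoneme/syllable counts.

These small hermetic resources back the lexicon-based tagger, the fluency
scorers, the grapheme-to-phoneme counter and the synthetic transcript
generator.  They are deliberately compact: the synthetic cohorts draw their
vocabulary from the same lists, so tagger coverage on generated text is
complete by construction.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Penn-Treebank tag lexicon.  Coarse classes used by the feature definitions
# are derived from these tags via TAG_TO_CLASS below.
# ---------------------------------------------------------------------------

_NOUNS = """
boy girl woman man mother sister brother cookie jar stool sink water plate
cup dish window curtain kitchen counter floor garden tree house dog cat bird
fish kite picnic basket blanket sandwich bottle wine book flag boat lake
shore radio car chair table spoon bread butter apple face hand arm leg shoe
dress shirt hat ladder wall door cabinet towel cloth grass sky cloud sun
family child person friend week day morning evening store road picture
drawing scene thing time way place work food drink music game ball wagon
pail shovel sail person people mess trouble overflow tap faucet
""".split()

_VERBS_BASE = """
run sit stand take reach fall wash dry spill climb play read fly sail look
watch see smile laugh talk speak hold give open close pour drink eat steal
hand point wave lean tip dry stand go come want try seem appear happen begin
start stop help make get put let think know feel say tell ask wear carry
""".split()

_VERBS_VBZ = """
runs sits stands takes reaches falls washes dries spills climbs plays reads
flies sails looks watches sees smiles laughs talks speaks holds gives opens
closes pours drinks eats steals hands points waves leans tips goes comes
wants tries seems appears happens begins starts stops helps makes gets puts
lets thinks knows feels says tells asks wears carries is has does
""".split()

_VERBS_VBD = """
ran sat stood took reached fell washed dried spilled climbed played read
flew sailed looked watched saw smiled laughed talked spoke held gave opened
closed poured drank ate stole handed pointed waved leaned tipped went came
wanted tried seemed appeared happened began started stopped helped made got
put let thought knew felt said told asked wore carried was were had did
""".split()

_VERBS_VBG = """
running sitting standing taking reaching falling washing drying spilling
climbing playing reading flying sailing looking watching seeing smiling
laughing talking speaking holding giving opening closing pouring drinking
eating stealing handing pointing waving leaning tipping going coming wanting
trying seeming appearing happening beginning starting stopping helping
making getting putting letting thinking knowing feeling saying telling
asking wearing carrying being having doing
""".split()

_ADJECTIVES = """
little big small old young tall short happy sad busy quiet loud full empty
wet dry dirty clean open closed high low nice pretty warm cold sunny windy
dark light red blue green white black wooden broken careful careless hungry
thirsty tired awake ready late early good bad fine lovely
""".split()

_ADVERBS = """
quickly slowly quietly loudly carefully carelessly happily sadly very quite
really almost nearly just only also too again still already soon now then
there here away outside inside maybe perhaps probably certainly clearly
""".split()

_PREPOSITIONS = """
in on at by with from to of over under near behind beside between into onto
through across around during about for after before up down off out
""".split()

_DETERMINERS = "the a an this that these those some any each every no another".split()

_PRONOUNS_PRP = "i you he she it we they me him her us them himself herself itself".split()
_PRONOUNS_PRPS = "my your his her its our their".split()

_COORD_CONJ = "and or but nor yet so".split()
_SUBORD_CONJ = """
because although though while if since unless until when whenever where as
whereas that whether
""".split()

_MODALS = "can could will would shall should may might must".split()

INTERJECTIONS = "uh um er ah hmm huh oh hm erm".split()

_EXISTENTIAL = ["there"]  # tagged EX only sentence-initially before a verb; kept RB here

TAG_LEXICON: dict[str, str] = {}
for _w in _NOUNS:
    TAG_LEXICON[_w] = "NN"
for _w in _VERBS_BASE:
    TAG_LEXICON.setdefault(_w, "VB")
for _w in _VERBS_VBZ:
    TAG_LEXICON[_w] = "VBZ"
for _w in _VERBS_VBD:
    TAG_LEXICON[_w] = "VBD"
for _w in _VERBS_VBG:
    TAG_LEXICON[_w] = "VBG"
for _w in _ADJECTIVES:
    TAG_LEXICON.setdefault(_w, "JJ")
for _w in _ADVERBS:
    TAG_LEXICON.setdefault(_w, "RB")
for _w in _PREPOSITIONS:
    TAG_LEXICON.setdefault(_w, "IN")
for _w in _DETERMINERS:
    TAG_LEXICON[_w] = "DT"
for _w in _PRONOUNS_PRP:
    TAG_LEXICON[_w] = "PRP"
for _w in _PRONOUNS_PRPS:
    TAG_LEXICON[_w] = "PRP$"
for _w in _COORD_CONJ:
    TAG_LEXICON[_w] = "CC"
for _w in _MODALS:
    TAG_LEXICON[_w] = "MD"
for _w in INTERJECTIONS:
    TAG_LEXICON[_w] = "UH"

# Subordinating conjunctions share the IN tag in PTB; the ratio feature needs
# the explicit membership list.
SUBORDINATE_CONJUNCTIONS = frozenset(_SUBORD_CONJ)
COORDINATE_CONJUNCTIONS = frozenset(_COORD_CONJ)
for _w in _SUBORD_CONJ:
    TAG_LEXICON.setdefault(_w, "IN")

# Mapping from PTB tags to the coarse classes named by the feature contract.
TAG_TO_CLASS: dict[str, str] = {
    "NN": "noun", "NNS": "noun", "NNP": "propn", "NNPS": "propn",
    "VB": "verb", "VBD": "verb", "VBG": "verb", "VBN": "verb",
    "VBP": "verb", "VBZ": "verb",
    "MD": "modal",
    "JJ": "adj", "JJR": "adj", "JJS": "adj",
    "RB": "adv", "RBR": "adv", "RBS": "adv",
    "IN": "prep",          # refined to sconj via SUBORDINATE_CONJUNCTIONS
    "CC": "cconj",
    "DT": "det",
    "PRP": "pron", "PRP$": "pron", "WP": "pron",
    "UH": "intj",
    "CD": "num",
}

# ---------------------------------------------------------------------------
# Number words (phonemic-fluency exclusion rule).
# ---------------------------------------------------------------------------

NUMBER_WORDS = frozenset("""
zero one two three four five six seven eight nine ten eleven twelve thirteen
fourteen fifteen sixteen seventeen eighteen nineteen twenty thirty forty
fifty sixty seventy eighty ninety hundred thousand million first second
third fourth fifth
""".split())

# ---------------------------------------------------------------------------
# Animal dictionary (semantic-fluency answer key).  Multiword entries are
# matched greedily by the scorer.
# ---------------------------------------------------------------------------

ANIMALS = frozenset("""
dog cat horse cow pig sheep goat chicken duck goose rabbit mouse rat lion
tiger bear elephant giraffe zebra monkey gorilla wolf fox deer moose elk
squirrel hedgehog badger otter beaver seal walrus whale dolphin shark fish
salmon trout eel octopus crab lobster shrimp snail frog toad snake lizard
turtle crocodile alligator eagle hawk owl crow raven sparrow robin pigeon
penguin ostrich flamingo swan bat camel llama alpaca donkey mule hamster
gerbil ferret kangaroo koala panda sloth armadillo anteater porcupine skunk
raccoon weasel mink hyena jackal cheetah leopard jaguar panther lynx puma
""".split()) | frozenset(["polar bear", "guinea pig", "killer whale", "sea lion"])

# ---------------------------------------------------------------------------
# Phoneme counts for common words (grapheme-to-phoneme lexicon).  Out-of-
# lexicon words fall back to a documented letter-based estimate.
# ---------------------------------------------------------------------------

PHONEME_COUNTS: dict[str, int] = {
    "cat": 3, "dog": 3, "the": 2, "a": 1, "an": 2, "boy": 2, "girl": 3,
    "cookie": 4, "jar": 2, "water": 4, "is": 2, "was": 3, "are": 2,
    "running": 5, "sitting": 5, "and": 3, "on": 2, "in": 2, "to": 2,
    "of": 2, "with": 3, "she": 2, "he": 2, "it": 2, "they": 2, "uh": 1,
    "um": 2, "mother": 4, "sister": 5, "window": 5, "kitchen": 5,
    "little": 4, "big": 3, "house": 3, "tree": 3, "bird": 3, "fish": 3,
    "there": 3, "here": 3, "this": 3, "that": 3, "very": 4, "over": 3,
}

# Syllable-count exceptions for the dictionary-first syllable counter.
SYLLABLE_EXCEPTIONS: dict[str, int] = {
    "the": 1, "cookie": 2, "people": 2, "little": 2, "able": 2,
    "every": 2, "evening": 2, "interesting": 3, "family": 3,
    "business": 2, "vegetable": 4, "chocolate": 2, "camera": 2,
    "fire": 1, "hour": 1, "our": 1, "iron": 2, "quiet": 2, "science": 2,
}

# ---------------------------------------------------------------------------
# Sentence templates for the synthetic transcript generator: sequences of POS
# slots filled from the lexicon.  The slot names match TAG_LEXICON tags.
# ---------------------------------------------------------------------------

SENTENCE_TEMPLATES: list[list[str]] = [
    ["DT", "NN", "VBZ", "VBG", "IN", "DT", "NN"],
    ["DT", "JJ", "NN", "VBZ", "IN", "DT", "NN"],
    ["PRP", "VBD", "DT", "NN", "IN", "DT", "JJ", "NN"],
    ["DT", "NN", "VBD", "RB", "IN", "DT", "NN"],
    ["PRP", "VBZ", "VBG", "DT", "NN"],
    ["DT", "NN", "CC", "DT", "NN", "VBD", "IN", "DT", "NN"],
    ["PRP", "MD", "VB", "DT", "JJ", "NN"],
    ["SCONJ", "DT", "NN", "VBZ", "JJ", "PRP", "VBZ", "RB"],
    ["DT", "JJ", "JJ", "NN", "VBZ", "RB", "VBG"],
    ["PRP", "VBD", "CC", "VBD", "IN", "DT", "NN"],
]

DEFAULT_LEXICON_POOLS: dict[str, list[str]] = {
    "NN": _NOUNS,
    "VB": _VERBS_BASE,
    "VBZ": _VERBS_VBZ,
    "VBD": _VERBS_VBD,
    "VBG": _VERBS_VBG,
    "JJ": _ADJECTIVES,
    "RB": _ADVERBS,
    "IN": _PREPOSITIONS,
    "DT": _DETERMINERS,
    "PRP": _PRONOUNS_PRP,
    "CC": _COORD_CONJ,
    "MD": _MODALS,
    "SCONJ": _SUBORD_CONJ,
    "UH": INTERJECTIONS,
}

# The bundled English dictionary for words_not_in_dict_ratio is simply the
# union of everything above (configurable at call time).
ENGLISH_DICTIONARY = frozenset(TAG_LEXICON) | NUMBER_WORDS | frozenset(
    w for a in ANIMALS for w in a.split()
)
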