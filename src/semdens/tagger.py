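"""Pluggable POS-tagging and lemmatization backends.

The preprocessing stage only requires a backend that maps surface tokens to
the coarse tag set ``{NN, VB, JJ, RB, IN, CC, DT, PR, OTHER}`` together with a
lemma.  Research-grade pipelines would plug a constituency parser or a
statistical tagger in here; the built-in :class:`RuleBasedTagger` is a
self-contained lexicon-and-suffix backend that covers conversational English
well enough for the analyses in this package and requires no model download.

Any object with a ``tag_tokens(tokens) -> list[(surface, coarse_tag, lemma)]``
method and a ``name`` attribute is a valid backend; Penn-treebank backends can
reuse :func:`map_penn_tag` to coarsen their output.
"""

from __future__ import annotations

import re

COARSE_TAGS = ("NN", "VB", "JJ", "RB", "IN", "CC", "DT", "PR", "OTHER")
CONTENT_TAGS = ("NN", "VB", "JJ", "RB")


def map_penn_tag(tag: str) -> str:
    """Coarsen a Penn-treebank tag: NN*->NN, VB*->VB, JJ*->JJ, RB*->RB,
    IN->IN, CC->CC, DT->DT, PRP*->PR, everything else -> OTHER."""
    if tag.startswith("NN"):
        return "NN"
    if tag.startswith("VB"):
        return "VB"
    if tag.startswith("JJ"):
        return "JJ"
    if tag.startswith("RB"):
        return "RB"
    if tag == "IN":
        return "IN"
    if tag == "CC":
        return "CC"
    if tag == "DT":
        return "DT"
    if tag.startswith("PRP") or tag in ("WP", "WP$"):
        return "PR"
    return "OTHER"


_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "some",
                "any", "no", "every", "each", "either", "neither", "another"}
_PRONOUNS = {"i", "you", "he", "she", "it", "we", "they", "me", "him", "her",
             "us", "them", "myself", "yourself", "himself", "herself",
             "itself", "ourselves", "themselves", "mine", "yours", "his",
             "hers", "ours", "theirs", "who", "whom", "whose", "my", "your",
             "its", "our", "their", "one", "someone", "something", "anyone",
             "anything", "everyone", "everything", "nobody", "nothing"}
_PREPOSITIONS = {"in", "on", "at", "by", "with", "from", "of", "to", "for",
                 "about", "over", "under", "after", "before", "during",
                 "through", "between", "against", "into", "onto", "without",
                 "within", "among", "around", "near", "off", "since", "until",
                 "toward", "towards", "upon", "if", "because", "while",
                 "although", "though", "unless", "whether", "than", "as"}
_CONJUNCTIONS = {"and", "or", "but", "nor", "so", "yet", "plus"}
_OTHER_FUNCTION = {"not", "n't", "will", "would", "can", "could", "shall",
                   "should", "may", "might", "must", "up", "down", "out",
                   "there", "then", "when", "where", "how", "why", "what",
                   "which", "oh", "um", "uh", "yeah", "okay", "ok", "hmm",
                   "mm", "huh"}

# Irregular verb forms -> lemma.  Conversational high-frequency verbs only;
# regular inflections are handled by suffix stripping.
_IRREGULAR_VERBS = {
    "am": "be", "is": "be", "are": "be", "was": "be", "were": "be",
    "been": "be", "being": "be", "be": "be",
    "has": "have", "had": "have", "have": "have", "having": "have",
    "does": "do", "did": "do", "done": "do", "do": "do", "doing": "do",
    "says": "say", "said": "say", "say": "say",
    "goes": "go", "went": "go", "gone": "go", "go": "go", "going": "go",
    "gets": "get", "got": "get", "gotten": "get", "get": "get",
    "makes": "make", "made": "make", "make": "make",
    "knows": "know", "knew": "know", "known": "know", "know": "know",
    "thinks": "think", "thought": "think", "think": "think",
    "takes": "take", "took": "take", "taken": "take", "take": "take",
    "sees": "see", "saw": "see", "seen": "see", "see": "see",
    "comes": "come", "came": "come", "come": "come",
    "gives": "give", "gave": "give", "given": "give", "give": "give",
    "finds": "find", "found": "find", "find": "find",
    "tells": "tell", "told": "tell", "tell": "tell",
    "feels": "feel", "felt": "feel", "feel": "feel",
    "leaves": "leave", "left": "leave", "leave": "leave",
    "keeps": "keep", "kept": "keep", "keep": "keep",
    "begins": "begin", "began": "begin", "begun": "begin", "begin": "begin",
    "hears": "hear", "heard": "hear", "hear": "hear",
    "speaks": "speak", "spoke": "speak", "spoken": "speak", "speak": "speak",
    "means": "mean", "meant": "mean", "mean": "mean",
    "runs": "run", "ran": "run", "run": "run",
    "sits": "sit", "sat": "sit", "sit": "sit",
    "stands": "stand", "stood": "stand", "stand": "stand",
    "loses": "lose", "lost": "lose", "lose": "lose",
    "puts": "put", "put": "put",
    "lets": "let", "let": "let",
    "talks": "talk", "talked": "talk", "talking": "talk", "talk": "talk",
}

_ADJ_SUFFIXES = ("ous", "ful", "ive", "able", "ible", "ical", "ish", "less",
                 "ary", "al", "ic")
_COMMON_ADJECTIVES = {"good", "bad", "big", "small", "loud", "quiet", "new",
                      "old", "strange", "weird", "funny", "little", "long",
                      "short", "high", "low", "real", "whole", "same",
                      "different", "hard", "easy", "scary", "dark", "bright",
                      "crazy", "happy", "sad", "angry", "afraid", "far",
                      "digital", "entire", "other", "last", "next", "few",
                      "many", "much", "more", "most"}
_COMMON_ADVERBS = {"very", "really", "just", "now", "never", "always",
                   "sometimes", "often", "again", "here", "too", "also",
                   "maybe", "perhaps", "away", "back", "still", "even",
                   "almost", "already", "soon", "quite", "rather", "entirely"}


def _strip_plural(word: str) -> str:
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("es") and len(word) > 3 and word[-3] in "sxz":
        return word[:-2]
    if word.endswith("s") and not word.endswith("ss") and len(word) > 3:
        return word[:-1]
    return word


def _verb_lemma(word: str) -> str:
    if word in _IRREGULAR_VERBS:
        return _IRREGULAR_VERBS[word]
    if word.endswith("ying") and len(word) > 5:
        return word[:-4] + "y"
    if word.endswith("ing") and len(word) > 4:
        stem = word[:-3]
        if len(stem) > 2 and stem[-1] == stem[-2]:  # running -> run
            stem = stem[:-1]
        return stem
    if word.endswith("ied") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("ed") and len(word) > 3:
        stem = word[:-2]
        if len(stem) > 2 and stem[-1] == stem[-2]:
            stem = stem[:-1]
        if stem.endswith(("at", "iv", "uc", "id")):  # created -> create
            stem = stem + "e"
        return stem
    return _strip_plural(word)


class RuleBasedTagger:
    """Lexicon + suffix heuristics over the coarse tag set.

    Deterministic, dependency-free, and intentionally simple: unknown words
    default to nouns, which matches the behaviour wanted for the synthetic
    pseudo-word vocabularies used throughout the test fixtures.
    """

    name = "rule-based/builtin"

    def tag_tokens(self, tokens: list[str]) -> list[tuple[str, str, str]]:
        out = []
        for tok in tokens:
            word = tok.lower()
            out.append((tok,) + self._tag_word(word))
        return out

    def _tag_word(self, word: str) -> tuple[str, str]:
        if not any(ch.isalpha() for ch in word):
            return "OTHER", word
        if word in _DETERMINERS:
            return "DT", word
        if word in _PRONOUNS:
            return "PR", word
        if word in _PREPOSITIONS:
            return "IN", word
        if word in _CONJUNCTIONS:
            return "CC", word
        if word in _OTHER_FUNCTION:
            return "OTHER", word
        if word in _IRREGULAR_VERBS:
            return "VB", _IRREGULAR_VERBS[word]
        if word in _COMMON_ADVERBS or (word.endswith("ly") and len(word) > 3):
            return "RB", word
        if word in _COMMON_ADJECTIVES:
            return "JJ", word
        if word.endswith(("ing", "ed")) and len(word) > 4:
            return "VB", _verb_lemma(word)
        if word.endswith(_ADJ_SUFFIXES) and len(word) > 4:
            return "JJ", word
        return "NN", _strip_plural(word)


_TOKEN_RE = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)?|\d+(?:\.\d+)?")


def word_tokenize(text: str) -> list[str]:
    """Split text into word tokens, dropping punctuation."""
    return _TOKEN_RE.findall(text)


_SENT_RE = re.compile(r"[^.!?]+[.!?]*")


def sentence_split(text: str) -> list[str]:
    """Split text into sentences on terminal punctuation."""
    return [s.strip() for s in _SENT_RE.findall(text) if s.strip()]
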