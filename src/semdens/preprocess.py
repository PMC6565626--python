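"""Transcript preprocessing: speaker separation, sentence tokenization,
POS tagging, content-word extraction, and the POS-preserving shuffle control.

A transcript enters as a sequence of :class:`Utterance` records (participant
or interviewer speech).  It leaves as :class:`ContentSentence` records whose
tokens are POS-prefixed lemmas (``NN_voice``) — the keys used to look up word
embeddings downstream.  The shuffle control permutes content words across a
transcript within each POS category, destroying sentence-level word grouping
while preserving sentence lengths, POS patterns, and the per-POS word
multiset; it is the null model against which semantic density is validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .tagger import CONTENT_TAGS, RuleBasedTagger, sentence_split, word_tokenize

logger = logging.getLogger(__name__)

SPEAKER_ROLES = ("participant", "interviewer")

DEFAULT_MAX_SENTENCE_LEN = 60


@dataclass(frozen=True)
class Utterance:
    participant_id: str
    speaker: str
    text: str

    def __post_init__(self):
        if self.speaker not in SPEAKER_ROLES:
            raise InvalidInputError(
                f"unknown speaker role {self.speaker!r}; expected one of {SPEAKER_ROLES}")
        if not self.text.strip():
            raise InvalidInputError("utterance text is empty")


@dataclass(frozen=True)
class Token:
    surface: str
    tag: str
    lemma: str

    @property
    def key(self) -> str:
        """POS-prefixed lemma, the embedding lookup key (e.g. ``NN_voice``)."""
        return f"{self.tag}_{self.lemma}"


@dataclass(frozen=True)
class TaggedSentence:
    tokens: tuple[Token, ...]
    participant_id: str
    speaker: str

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class ContentSentence:
    """Content-word reduction of a sentence: ordered POS-prefixed lemma keys.

    ``n_content`` counts tokens with repetition — a repeated noun counts
    twice — because semantic density divides meaning components by the number
    of content *tokens* in the sentence.
    """

    content_keys: tuple[str, ...]
    participant_id: str = ""

    @property
    def n_content(self) -> int:
        return len(self.content_keys)

    def tags(self) -> tuple[str, ...]:
        return tuple(k.split("_", 1)[0] for k in self.content_keys)

    def words(self) -> tuple[str, ...]:
        return tuple(k.split("_", 1)[1] for k in self.content_keys)


def separate_speakers(utterances: Sequence[Utterance], role: str) -> list[Utterance]:
    """Return the utterances with the requested speaker role, order preserved."""
    if role not in SPEAKER_ROLES:
        raise InvalidInputError(
            f"unknown speaker role {role!r}; expected one of {SPEAKER_ROLES}")
    return [u for u in utterances if u.speaker == role]


def tokenize_and_tag(utterance: Utterance,
                     max_len: int = DEFAULT_MAX_SENTENCE_LEN,
                     backend=None) -> list[TaggedSentence]:
    """Split an utterance into sentences and POS-tag/lemmatize each token.

    Sentences longer than ``max_len`` tokens are dropped (not truncated) and
    logged.  The tagging backend is pluggable; the built-in rule-based tagger
    is the default.
    """
    if backend is None:
        backend = RuleBasedTagger()
    out: list[TaggedSentence] = []
    n_dropped = 0
    for raw in sentence_split(utterance.text):
        words = word_tokenize(raw)
        if not words:
            continue
        if len(words) > max_len:
            n_dropped += 1
            continue
        tagged = backend.tag_tokens(words)
        tokens = tuple(Token(surface, tag, lemma) for surface, tag, lemma in tagged)
        out.append(TaggedSentence(tokens=tokens,
                                  participant_id=utterance.participant_id,
                                  speaker=utterance.speaker))
    if n_dropped:
        logger.info("dropped %d over-length sentence(s) (> %d tokens) for %s",
                    n_dropped, max_len, utterance.participant_id)
    return out


def extract_content(sentence: TaggedSentence) -> ContentSentence:
    """Keep only noun/verb/adjective/adverb tokens as POS-prefixed lemmas."""
    keys = tuple(t.key for t in sentence.tokens if t.tag in CONTENT_TAGS)
    return ContentSentence(content_keys=keys, participant_id=sentence.participant_id)


def preprocess_utterances(utterances: Sequence[Utterance],
                          role: str = "participant",
                          max_len: int = DEFAULT_MAX_SENTENCE_LEN,
                          backend=None) -> dict[str, list[ContentSentence]]:
    """Full preprocessing: speaker separation -> tagged sentences -> content
    sentences, grouped by participant.  Empty content sentences are kept out.
    """
    per_participant: dict[str, list[ContentSentence]] = {}
    for utt in separate_speakers(utterances, role):
        for tagged in tokenize_and_tag(utt, max_len=max_len, backend=backend):
            content = extract_content(tagged)
            if content.n_content:
                per_participant.setdefault(utt.participant_id, []).append(content)
    return per_participant


def pos_shuffle(transcript: Sequence[ContentSentence], seed: int) -> list[ContentSentence]:
    """Shuffle content words across a transcript within POS categories.

    Verbs are switched with verbs, nouns with nouns, and so on: every
    sentence keeps its length and its per-position POS pattern, and the
    transcript-level word multiset per POS is unchanged.  Deterministic for a
    fixed seed.
    """
    if not transcript:
        raise InvalidInputError("pos_shuffle requires at least one content sentence")
    rng = np.random.default_rng(seed)
    pools: dict[str, list[str]] = {}
    for sent in transcript:
        for key in sent.content_keys:
            tag = key.split("_", 1)[0]
            pools.setdefault(tag, []).append(key)
    for tag in sorted(pools):
        perm = rng.permutation(len(pools[tag]))
        pools[tag] = [pools[tag][i] for i in perm]
    cursors = {tag: 0 for tag in pools}
    shuffled: list[ContentSentence] = []
    for sent in transcript:
        new_keys = []
        for key in sent.content_keys:
            tag = key.split("_", 1)[0]
            new_keys.append(pools[tag][cursors[tag]])
            cursors[tag] += 1
        shuffled.append(ContentSentence(content_keys=tuple(new_keys),
                                        participant_id=sent.participant_id))
    return shuffled


def pos_shuffle_cohort(transcripts: dict[str, list[ContentSentence]],
                       seed: int,
                       scope: str = "participant") -> dict[str, list[ContentSentence]]:
    """Shuffle every transcript in a cohort.

    ``scope='participant'`` (default) shuffles within each participant's
    transcript, keeping per-participant word inventories fixed;
    ``scope='cohort'`` pools all participants' content words before
    shuffling.
    """
    if scope == "participant":
        rng = np.random.default_rng(seed)
        out = {}
        for pid in sorted(transcripts):
            out[pid] = pos_shuffle(transcripts[pid], int(rng.integers(2**31)))
        return out
    if scope == "cohort":
        order = [(pid, len(transcripts[pid])) for pid in sorted(transcripts)]
        flat = [s for pid, _ in order for s in transcripts[pid]]
        shuffled = pos_shuffle(flat, seed)
        out, i = {}, 0
        for pid, n in order:
            out[pid] = shuffled[i:i + n]
            i += n
        return out
    raise InvalidInputError(f"unknown shuffle scope {scope!r}")


# ---------------------------------------------------------------------------
# Transcript I/O

def read_transcripts(path: str | Path) -> list[Utterance]:
    """Read utterances from a delimited table or a prefixed plain-text file.

    Tables (``.csv``/``.tsv``) need columns ``participant_id``, ``speaker``,
    ``utterance_text``.  Plain text uses ``## participant_id`` section headers
    with ``P:`` / ``I:`` line prefixes for participant/interviewer speech.
    """
    path = Path(path)
    if path.suffix.lower() in (".csv", ".tsv"):
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        df = pd.read_csv(path, sep=sep, dtype=str)
        required = {"participant_id", "speaker", "utterance_text"}
        if not required.issubset(df.columns):
            raise InvalidInputError(
                f"transcript table must have columns {sorted(required)}")
        return [Utterance(str(r.participant_id), str(r.speaker), str(r.utterance_text))
                for r in df.itertuples()]
    utterances: list[Utterance] = []
    current = None
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            current = line[2:].strip()
        elif line.startswith("P:") or line.startswith("I:"):
            if current is None:
                raise InvalidInputError("utterance before any '## participant' header")
            role = "participant" if line.startswith("P:") else "interviewer"
            text = line[2:].strip()
            if text:
                utterances.append(Utterance(current, role, text))
    return utterances


def write_tagged_sentences(sentences: Iterable[TaggedSentence], path: str | Path) -> None:
    """Write tagged sentences as line-delimited JSON-style records."""
    import json
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            rec = {"participant_id": s.participant_id, "speaker": s.speaker,
                   "tokens": [[t.surface, t.tag, t.lemma] for t in s.tokens]}
            fh.write(json.dumps(rec) + "\n")
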