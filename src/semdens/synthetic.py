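"""Synthetic fixtures with known ground truth.

Generates (i) embedding spaces whose vocabulary is organised into semantic
concepts with a controllable within-concept cosine, (ii) two-group cohorts
of speech transcripts with planted effects, and (iii) baseline corpora, so
that every stage of the pipeline is testable without any data download.

Planted effects
---------------
*Density effect*: with probability ``density_effect`` a positive-group
sentence is *redundant* — all of its words are drawn (with replacement) from
a single randomly chosen concept, so the sentence's embeddings overlap
heavily and vector unpacking needs fewer meaning components than there are
tokens.  Negative-group transcripts are generated by the *same* word-draw
process and then scrambled: the transcript's tokens are redistributed
randomly across its sentences (lengths preserved).  Both groups therefore
share one word-inventory distribution and differ only in how words are
grouped into sentences — semantic density as an organizational property —
so a POS-preserving shuffle makes the groups exchangeable by construction.

*Concept effect*: positive-group word draws are mixed toward a designated
target concept with weight ``concept_effect`` (a ``(1-e)*uniform + e*target``
mixture), raising the group's sentence cosines to that concept's direction
without requiring any particular word to be spoken.

The vocabulary consists of pronounceable CV pseudo-words that the built-in
tagger labels as nouns, so cohorts round-trip through the real preprocessing
path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .embeddings import EmbeddingSpace
from .errors import InvalidInputError
from .preprocess import ContentSentence, Utterance

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
_BANNED_SUFFIXES = ("ed", "ing", "ly", "es")


def _pseudo_word(idx: int) -> str:
    """Deterministic CV-syllable pseudo-word for a vocabulary index."""
    syllables = []
    i = idx
    for _ in range(3):
        c = _CONSONANTS[i % len(_CONSONANTS)]
        i //= len(_CONSONANTS)
        v = _VOWELS[i % len(_VOWELS)]
        i //= len(_VOWELS)
        syllables.append(c + v)
    word = "".join(syllables)
    if word.endswith(_BANNED_SUFFIXES):
        word += "t"
    return word


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic cohort.

    Group sizes default to the 7-positive / 23-negative composition of a
    small clinical-high-risk training cohort; effects default to the strong
    settings used for planted-effect recovery checks.
    """
    n_words: int = 120
    dimension: int = 24
    n_concepts: int = 12
    within_concept_cosine: float = 0.8
    sentences_per_participant: int = 10
    words_per_sentence: tuple[int, int] = (4, 6)
    group_sizes: tuple[int, int] = (7, 23)
    density_effect: float = 0.8
    concept_effect: float = 0.8
    target_concept: int = 0
    interviewer_utterances: int = 2
    zipf_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_concepts > self.n_words:
            raise InvalidInputError("n_concepts must be <= n_words")
        for name in ("n_words", "dimension", "n_concepts",
                     "sentences_per_participant"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if not 0 <= self.density_effect <= 1:
            raise InvalidInputError("density_effect must be in [0, 1]")
        if self.concept_effect < 0:
            raise InvalidInputError("concept_effect must be >= 0")
        if not 0 <= self.within_concept_cosine < 1:
            raise InvalidInputError("within_concept_cosine must be in [0, 1)")
        if min(self.group_sizes) < 1:
            raise InvalidInputError("both group sizes must be >= 1")
        if not 1 <= self.words_per_sentence[0] <= self.words_per_sentence[1]:
            raise InvalidInputError("invalid words_per_sentence range")


def make_embedding_space(spec: FixtureSpec) -> EmbeddingSpace:
    """Unit-vector vocabulary organised into concepts.

    Concept centers are mutually orthogonal (QR of a random Gaussian
    matrix); each word is sqrt(rho)*center + sqrt(1-rho)*orthogonal noise, so
    within-concept pairwise cosines concentrate around rho =
    ``within_concept_cosine`` and cross-concept cosines around 0.
    Frequencies follow a Zipf law over the frequency rank.  Deterministic
    for a fixed seed.
    """
    if spec.dimension < spec.n_concepts:
        raise InvalidInputError(
            "dimension must be >= n_concepts for orthogonal concept centers")
    rng = np.random.default_rng(spec.seed)
    d = spec.dimension
    centers, _ = np.linalg.qr(rng.standard_normal((d, spec.n_concepts)))
    centers = centers.T  # (n_concepts, d), orthonormal rows

    concept_size = np.bincount(np.arange(spec.n_words) % spec.n_concepts)
    keys, rows, concept_of = [], [], {}
    alpha = np.sqrt(spec.within_concept_cosine)
    beta = np.sqrt(1.0 - spec.within_concept_cosine)
    for w in range(spec.n_words):
        c = w % spec.n_concepts
        center = centers[c]
        if concept_size[c] == 1:
            # singleton concept: the center itself (no within-concept pairs)
            vec = center.copy()
        else:
            noise = rng.standard_normal(d)
            noise -= (noise @ center) * center
            noise /= np.linalg.norm(noise)
            vec = alpha * center + beta * noise
            vec /= np.linalg.norm(vec)
        key = f"NN_{_pseudo_word(w)}"
        keys.append(key)
        rows.append(vec)
        concept_of[key] = c

    ranks = rng.permutation(spec.n_words) + 1
    freqs = {k: max(1, int(10_000 / r ** spec.zipf_exponent))
             for k, r in zip(keys, ranks)}
    space = EmbeddingSpace(keys, np.array(rows), freqs)
    space.concept_of = concept_of  # ground-truth concept labels
    space.concept_centers = centers
    return space


def _sentence_words(rng, spec: FixtureSpec, space: EmbeddingSpace,
                    positive: bool) -> tuple[list[str], bool, int]:
    """Draw one sentence's word keys; returns (keys, redundant, concept)."""
    keys = space.keys
    lo, hi = spec.words_per_sentence
    length = int(rng.integers(lo, hi + 1))
    by_concept: dict[int, list[str]] = {}
    for k in keys:
        by_concept.setdefault(space.concept_of[k], []).append(k)

    if positive and rng.random() < spec.density_effect:
        # redundant sentence: all words drawn (with replacement) from one
        # concept, mixing semantic near-duplicates with occasional literal
        # repeats — the two faces of redundant speech.  Each sentence uses
        # its own random concept so the transcript-level word inventory
        # stays close to the null group's.
        weights = np.ones(spec.n_concepts)
        if spec.concept_effect > 0:
            weights[spec.target_concept] += spec.concept_effect * spec.n_concepts
        concept = int(rng.choice(spec.n_concepts, p=weights / weights.sum()))
        pool = by_concept[concept]
        words = [pool[i] for i in rng.integers(0, len(pool), size=length)]
        return words, True, concept

    if positive and spec.concept_effect > 0:
        e = min(spec.concept_effect, 1.0)
        target_pool = by_concept[spec.target_concept]
        words = []
        for _ in range(length):
            if rng.random() < e / 2:
                words.append(target_pool[int(rng.integers(len(target_pool)))])
            else:
                words.append(keys[int(rng.integers(len(keys)))])
        return words, False, -1

    words = [keys[i] for i in rng.integers(0, len(keys), size=length)]
    return words, False, -1


@dataclass
class Cohort:
    utterances: list[Utterance]
    labels: dict[str, int]
    ground_truth: pd.DataFrame
    spec: FixtureSpec

    def participant_sentences(self) -> dict[str, list[ContentSentence]]:
        """Ground-truth content sentences (bypassing the tagger), per
        participant, participant speech only."""
        out: dict[str, list[ContentSentence]] = {}
        for row in self.ground_truth.itertuples():
            out.setdefault(row.participant_id, []).append(
                ContentSentence(content_keys=tuple(row.word_keys.split()),
                                participant_id=row.participant_id))
        return out


def make_cohort(spec: FixtureSpec, space: EmbeddingSpace) -> Cohort:
    """Two-group cohort of transcripts with planted effects.

    Positive participants carry the density effect (concept-concentrated
    sentences) and the concept effect (draws biased toward the target
    concept).  Negative participants run the same concentration process
    minus the concept bias, and their transcript is then scrambled — tokens
    redistributed randomly across sentences with lengths preserved — so the
    two groups share one word-inventory distribution and differ only in
    sentence organization.  The ground-truth table records, per sentence,
    the drawn keys, token/distinct counts, the redundancy flag and concept.
    A couple of interviewer utterances per participant (independent uniform
    draws) exercise speaker separation.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_pos, n_neg = spec.group_sizes
    utterances: list[Utterance] = []
    labels: dict[str, int] = {}
    records = []
    null_spec = replace(spec, density_effect=0.0, concept_effect=0.0)
    neg_spec = replace(spec, concept_effect=0.0)
    for label, n in [(1, n_pos), (0, n_neg)]:
        for i in range(n):
            pid = f"{'conv' if label else 'ctrl'}{i:03d}"
            labels[pid] = label
            draw_spec = spec if label else neg_spec
            sentences = []
            for j in range(spec.sentences_per_participant):
                words, redundant, concept = _sentence_words(
                    rng, draw_spec, space, positive=True)
                sentences.append((words, redundant, concept))
            if not label:
                # scramble grouping: pool the transcript's tokens and re-deal
                pool = [w for words, _, _ in sentences for w in words]
                perm = rng.permutation(len(pool))
                pool = [pool[k] for k in perm]
                redealt, start = [], 0
                for words, _, _ in sentences:
                    redealt.append((pool[start:start + len(words)], False, -1))
                    start += len(words)
                sentences = redealt
            for j, (words, redundant, concept) in enumerate(sentences):
                text = " ".join(k.split("_", 1)[1] for k in words) + "."
                utterances.append(Utterance(pid, "participant", text))
                records.append({
                    "participant_id": pid, "sentence_idx": j, "label": label,
                    "n_tokens": len(words), "n_distinct": len(set(words)),
                    "redundant": redundant, "concept": concept,
                    "word_keys": " ".join(words)})
            for _ in range(spec.interviewer_utterances):
                words, _, _ = _sentence_words(rng, null_spec, space, positive=False)
                text = " ".join(k.split("_", 1)[1] for k in words) + "."
                utterances.append(Utterance(pid, "interviewer", text))
    return Cohort(utterances=utterances, labels=labels,
                  ground_truth=pd.DataFrame(records), spec=spec)


def make_baseline_corpus(spec: FixtureSpec, space: EmbeddingSpace,
                         n_documents: int = 50,
                         sentences_per_document: int | None = None,
                         target_weight: float = 0.0) -> list[str]:
    """Baseline documents emulating the norm corpus, one contributor per
    line-delimited document.

    Words are independent uniform draws, with the target concept's words
    down-weighted by ``target_weight``: 0 (default) gives a norm corpus that
    never dwells on the cohort's planted distinctive topic — the situation
    that makes base-rate contrast informative — while 1 reproduces the
    negative-group null process exactly (useful for null-centering checks).
    """
    rng = np.random.default_rng(spec.seed + 2)
    n_sent = (sentences_per_document if sentences_per_document is not None
              else spec.sentences_per_participant)
    weights = np.ones(len(space.keys))
    for i, k in enumerate(space.keys):
        if space.concept_of[k] == spec.target_concept:
            weights[i] = target_weight
    weights = weights / weights.sum()
    lo, hi = spec.words_per_sentence
    docs = []
    for _ in range(n_documents):
        sents = []
        for _ in range(n_sent):
            length = int(rng.integers(lo, hi + 1))
            idx = rng.choice(len(space.keys), size=length, p=weights)
            sents.append(" ".join(space.keys[i].split("_", 1)[1]
                                  for i in idx) + ".")
        docs.append(" ".join(sents))
    return docs


def write_baseline_corpus(docs: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(docs) + "\n", encoding="utf-8")


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write transcripts (TSV), labels (TSV) and ground truth (TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [{"participant_id": u.participant_id, "speaker": u.speaker,
             "utterance_text": u.text} for u in cohort.utterances]
    pd.DataFrame(rows).to_csv(outdir / "transcripts.tsv", sep="\t", index=False)
    pd.DataFrame({"participant_id": list(cohort.labels),
                  "label": list(cohort.labels.values())}
                 ).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    cohort.ground_truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
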