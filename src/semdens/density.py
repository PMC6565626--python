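"""Semantic density via vector unpacking.

A sentence vector y is the unit-normalized sum of the word embeddings of its
content words.  Vector unpacking decomposes y over a candidate lexicon
X = {x_1, ..., x_n}: gradient descent on the Euclidean cost
E = 1/2 ||y - sum_i w_i x_i||^2 learns one scalar weight per word embedding,
and after each iteration t every weight below the growing threshold
t / (tau * max_iterations) is set exactly to zero, pruning the solution to a
small set of influential embeddings.  The surviving high-weight embeddings —
the sentence's *meaning components* — are selected by rank-ordering the
nonzero weights and choosing the two-group split that maximises the one-way
F ratio.  Semantic density is then

    D_j = m_j / n_j

meaning components per content token; a participant's mean density averages
D_j over their sentences.  Low density operationalizes poverty of content.

The comparator measures (idea density, information value) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .embeddings import EmbeddingSpace, vector_length
from .errors import (InvalidInputError, NumericInstabilityError, SkipSentence)
from .preprocess import ContentSentence, TaggedSentence

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SentenceVector:
    """Unit-norm resultant of a sentence's content-word embeddings."""
    vector: np.ndarray
    word_keys: tuple[str, ...]
    n_content: int


@dataclass(frozen=True)
class UnpackingConfig:
    """Parameters of the unpacking descent and component selection.

    ``tau`` and ``max_iterations`` control the prune schedule: the threshold
    at iteration t is t / (tau * max_iterations), reaching 1/tau at the end.
    ``prune`` is ``'signed'`` (weights below the threshold, negatives
    included, are zeroed — the default) or ``'magnitude'``.
    ``convergence_tol`` enables a safe early stop: descent halts once the
    per-iteration cost change is below it AND no surviving weight lies below
    the final threshold (so no future pruning is pending); set to 0 to run
    the full schedule unconditionally.
    """
    learning_rate: float = 0.01
    tau: float = 100.0
    max_iterations: int = 5000
    candidate_keys: tuple[str, ...] | None = None
    low_density_cutoff: float = 0.25
    prune: str = "signed"
    convergence_tol: float = 1e-10
    equal_weight_tol: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise InvalidInputError("tau must be positive")
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be >= 1")
        if not 0 < self.low_density_cutoff < 1:
            raise InvalidInputError("low_density_cutoff must be in (0, 1)")
        if self.learning_rate <= 0:
            raise InvalidInputError("learning_rate must be positive")
        if self.prune not in ("signed", "magnitude"):
            raise InvalidInputError("prune must be 'signed' or 'magnitude'")

    @classmethod
    def desk_scale(cls, **overrides) -> "UnpackingConfig":
        """Configuration tuned for the small synthetic embedding spaces used
        in tests and examples (about 100 words in two dozen dimensions).

        Uses a larger learning rate and fewer iterations than the full-scale
        defaults; the rate stays below the descent stability bound
        2/lambda_max of the candidate Gram matrix, which for concept
        clusters of ~10 words at within-cosine 0.8 is about 0.24.
        """
        params = dict(learning_rate=0.1, max_iterations=300)
        params.update(overrides)
        return cls(**params)


@dataclass
class UnpackingResult:
    weights: dict[str, float]
    estimate: np.ndarray
    final_cost: float
    nonzero_count: int
    cost_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    selected_components: frozenset[str] = frozenset()
    m: int = 0
    density: float = float("nan")
    repartitioned: bool = False


def compose_sentence_vector(sentence: ContentSentence,
                            space: EmbeddingSpace) -> SentenceVector:
    """Sum the embeddings of in-vocabulary content keys and unit-normalize.

    Out-of-vocabulary keys are skipped and logged.  A sentence with no
    in-vocabulary key, or a zero resultant, raises :class:`SkipSentence`.
    """
    in_vocab = [k for k in sentence.content_keys if k in space]
    oov = len(sentence.content_keys) - len(in_vocab)
    if oov:
        logger.debug("skipping %d OOV key(s) in sentence of %s",
                     oov, sentence.participant_id)
    if not in_vocab:
        raise SkipSentence("no content key found in embedding space")
    resultant = space.vectors(in_vocab).sum(axis=0)
    norm = np.linalg.norm(resultant)
    if norm == 0:
        raise SkipSentence("content-word embeddings sum to the zero vector")
    return SentenceVector(vector=resultant / norm,
                          word_keys=tuple(in_vocab),
                          n_content=len(in_vocab))


def unpack(target: SentenceVector, space: EmbeddingSpace,
           config: UnpackingConfig = UnpackingConfig()) -> UnpackingResult:
    """Learn sparse weights reconstructing the sentence vector.

    Gradient descent on E = 1/2||y - X^T w||^2 with per-iteration threshold
    pruning; weights start at zero.  Returns weights, the estimate, the final
    cost and a per-100-iteration cost trace.  Component selection is applied
    separately (:func:`select_components`).
    """
    cand = config.candidate_keys if config.candidate_keys is not None else tuple(space.keys)
    if not cand:
        raise InvalidInputError("candidate vocabulary is empty")
    X = space.vectors(cand)                      # (n_cand, d)
    y = np.asarray(target.vector, dtype=float)
    w = np.zeros(len(cand))
    eta = config.learning_rate
    T = config.max_iterations
    final_threshold = 1.0 / config.tau

    trace: list[float] = []
    prev_cost = np.inf
    t_done = T
    for t in range(1, T + 1):
        r = y - X.T @ w
        cost = 0.5 * float(r @ r)
        if not np.isfinite(cost):
            raise NumericInstabilityError(
                f"unpacking diverged (non-finite cost) at learning_rate={eta}")
        if t % 100 == 1 or t == 1:
            trace.append(cost)
        w = w + eta * (X @ r)
        threshold = t / (config.tau * T)
        if config.prune == "signed":
            w[w < threshold] = 0.0
        else:
            w[np.abs(w) < threshold] = 0.0
        if config.convergence_tol > 0 and abs(prev_cost - cost) < config.convergence_tol:
            live = w[w != 0]
            pending = (live < final_threshold if config.prune == "signed"
                       else np.abs(live) < final_threshold)
            if not pending.any():
                t_done = t
                break
        prev_cost = cost

    r = y - X.T @ w
    final_cost = 0.5 * float(r @ r)
    trace.append(final_cost)
    weights = {k: float(wi) for k, wi in zip(cand, w) if wi != 0.0}
    return UnpackingResult(weights=weights, estimate=X.T @ w,
                           final_cost=final_cost,
                           nonzero_count=len(weights),
                           cost_trace=trace, n_iterations=t_done)


def _two_group_f(values: np.ndarray, split: int) -> float:
    """One-way F ratio for the partition values[:split] vs values[split:]."""
    g1, g2 = values[:split], values[split:]
    n1, n2 = len(g1), len(g2)
    gm = values.mean()
    m1, m2 = g1.mean(), g2.mean()
    msb = n1 * (m1 - gm) ** 2 + n2 * (m2 - gm) ** 2  # df = 1
    ssw = ((g1 - m1) ** 2).sum() + ((g2 - m2) ** 2).sum()
    dfw = n1 + n2 - 2
    if dfw <= 0:
        return float("nan")
    if ssw == 0:
        return float("inf")
    return float(msb / (ssw / dfw))


def select_components(weights: dict[str, float], n_content: int,
                      config: UnpackingConfig = UnpackingConfig()
                      ) -> tuple[frozenset[str], int, float, bool]:
    """Select high-weight meaning components by F-ratio partitioning.

    Nonzero weights are rank-ordered descending; every split into a high and
    a low group is scored by the two-group F ratio and the high group of the
    best split is kept.  If the resulting density m/n is at or below
    ``low_density_cutoff``, the split with the second-highest F ratio is used
    instead (once, no iteration) and the result is flagged ``repartitioned``.

    Degenerate cases: no nonzero weight -> :class:`SkipSentence`; exactly two
    nonzero weights, or (near-)identical weights where F is undefined ->
    select all nonzero weights.  F ties break toward the smaller high group.
    """
    items = sorted(((k, v) for k, v in weights.items() if v != 0.0),
                   key=lambda kv: (-abs(kv[1]), kv[0]))
    if not items:
        raise SkipSentence("no nonzero unpacking weight")
    if n_content < 1:
        raise SkipSentence("sentence has no content tokens")
    keys = [k for k, _ in items]
    vals = np.array([abs(v) for _, v in items])
    K = len(vals)

    def _all(repartitioned=False):
        return frozenset(keys), K, K / n_content, repartitioned

    if K <= 2:
        return _all()
    spread = (vals.max() - vals.min()) / vals.max() if vals.max() else 0.0
    if spread < config.equal_weight_tol:
        return _all()

    scored = []  # (F, split) for split = size of high group
    for split in range(1, K):
        f = _two_group_f(vals, split)
        if np.isnan(f):
            continue
        scored.append((f, split))
    if not scored:
        return _all()
    # best F first; ties toward smaller high group (fewer components)
    scored.sort(key=lambda fs: (-fs[0], fs[1]))
    best_split = scored[0][1]
    m = best_split
    repartitioned = False
    if m / n_content <= config.low_density_cutoff and len(scored) > 1:
        best_split = scored[1][1]
        m = best_split
        repartitioned = True
    return frozenset(keys[:best_split]), m, m / n_content, repartitioned


def semantic_density(m: int, n_content: int) -> float:
    """Meaning components per content token: D = m / n."""
    if n_content < 1:
        raise SkipSentence("sentence has no content tokens")
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    return m / n_content


def mean_density(densities: Sequence[float]) -> float:
    """Arithmetic mean of per-sentence densities."""
    if len(densities) == 0:
        raise SkipSentence("no sentence densities to average")
    return float(np.mean(densities))


def unpack_sentence(sentence: ContentSentence, space: EmbeddingSpace,
                    config: UnpackingConfig = UnpackingConfig()
                    ) -> UnpackingResult:
    """Compose -> unpack -> select -> density, for one content sentence."""
    sv = compose_sentence_vector(sentence, space)
    result = unpack(sv, space, config)
    selected, m, density, repart = select_components(
        result.weights, sv.n_content, config)
    result.selected_components = selected
    result.m = m
    result.density = density
    result.repartitioned = repart
    if m > sv.n_content:
        logger.info("m (%d) exceeds content-token count (%d); reported as computed",
                    m, sv.n_content)
    return result


@dataclass(frozen=True)
class ParticipantDensity:
    participant_id: str
    sentence_densities: tuple[float, ...]

    @property
    def sentence_count(self) -> int:
        return len(self.sentence_densities)

    @property
    def mean_density(self) -> float:
        return mean_density(self.sentence_densities)


def participant_density(participant_id: str,
                        sentences: Sequence[ContentSentence],
                        space: EmbeddingSpace,
                        config: UnpackingConfig = UnpackingConfig()
                        ) -> ParticipantDensity:
    """Per-sentence densities for one participant; skippable sentences are
    excluded and logged."""
    densities = []
    for sent in sentences:
        try:
            densities.append(unpack_sentence(sent, space, config).density)
        except SkipSentence as exc:
            logger.debug("skipping sentence for %s: %s", participant_id, exc)
    if not densities:
        raise SkipSentence(f"no usable sentence for participant {participant_id}")
    return ParticipantDensity(participant_id, tuple(densities))


# ---------------------------------------------------------------------------
# Comparator measures

IDEA_DENSITY_TAGS = ("VB", "JJ", "RB", "IN", "CC")


def idea_density(sentence: TaggedSentence) -> float:
    """Verbs + adjectives + adverbs + prepositions + conjunctions over total
    tokens — the proposition-count comparator."""
    if len(sentence) == 0:
        raise SkipSentence("empty sentence")
    hits = sum(1 for t in sentence.tokens if t.tag in IDEA_DENSITY_TAGS)
    return hits / len(sentence)


def information_value(sentence: ContentSentence,
                      space: EmbeddingSpace) -> tuple[float, float]:
    """Vector-length comparator on unnormalized embeddings.

    Returns (mean word-vector length, length of the resultant sum).
    """
    in_vocab = [k for k in sentence.content_keys if k in space]
    if not in_vocab:
        raise SkipSentence("no content key found in embedding space")
    vecs = space.vectors(in_vocab)
    mean_len = float(np.mean([vector_length(v) for v in vecs]))
    resultant_len = vector_length(vecs.sum(axis=0))
    return mean_len, resultant_len
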