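"""Latent content analysis.

The idea: a speaker's sentences, expressed as unit-norm sentence vectors, are
profiled against a large set of high-frequency *probe words* by retaining,
for each probe, the highest cosine between the probe's embedding and any of
the speaker's sentence vectors.  Probes a group leans toward can surface
themes the speakers never said aloud.  Contrasting a group profile against a
baseline-corpus profile with a tf-idf-style weighting keeps probes that are
close to the group but not to ordinary conversation; the top probes are
clustered in a 2-D reduction of their embeddings, and a cluster of interest
(e.g. voice/sound/hear/chant/loud) becomes a *concept vector* whose maximum
cosine with a participant's sentences is a scalar predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .density import SentenceVector
from .embeddings import EmbeddingSpace, unit_normalize
from .errors import DegenerateInputError, InvalidInputError

logger = logging.getLogger(__name__)

BASELINE_FLOOR = 1e-6


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity dot(u, v) / (||u|| ||v||)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateInputError("cosine undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass(frozen=True)
class ProbeProfile:
    """Per-entity map from probe word to cosine score."""
    entity_id: str
    scores: dict[str, float]
    aggregation: str  # 'max-over-sentences' | 'mean-over-entities'

    @property
    def probes(self) -> frozenset[str]:
        return frozenset(self.scores)


def probe_profile(probes: Sequence[str],
                  sentences: Sequence[SentenceVector],
                  space: EmbeddingSpace,
                  entity_id: str = "") -> ProbeProfile:
    """Max cosine between each probe's embedding and any sentence vector.

    Probes missing from the vocabulary are dropped and logged.
    """
    if not sentences:
        raise InvalidInputError("probe_profile requires at least one sentence")
    kept = [p for p in probes if p in space]
    dropped = len(probes) - len(kept)
    if dropped:
        logger.info("dropped %d probe(s) not in embedding space", dropped)
    if not kept:
        raise InvalidInputError("no probe found in embedding space")
    P = space.vectors(kept)
    P = P / np.linalg.norm(P, axis=1, keepdims=True)
    S = np.stack([unit_normalize(s.vector) for s in sentences])
    best = (P @ S.T).max(axis=1)
    return ProbeProfile(entity_id=entity_id,
                        scores={p: float(b) for p, b in zip(kept, best)},
                        aggregation="max-over-sentences")


def group_profile(profiles: Sequence[ProbeProfile],
                  entity_id: str = "group") -> ProbeProfile:
    """Per-probe arithmetic mean of scores across entities."""
    if not profiles:
        raise InvalidInputError("group_profile requires at least one profile")
    probes = profiles[0].probes
    for p in profiles[1:]:
        if p.probes != probes:
            raise InvalidInputError("probe sets differ across profiles")
    keys = sorted(probes)
    mat = np.array([[p.scores[k] for k in keys] for p in profiles])
    means = mat.mean(axis=0)
    return ProbeProfile(entity_id=entity_id,
                        scores=dict(zip(keys, means.tolist())),
                        aggregation="mean-over-entities")


@dataclass(frozen=True)
class ContrastMatrix:
    probes: tuple[str, ...]
    group_scores: np.ndarray
    baseline_scores: np.ndarray
    weighted_scores: dict[str, float]
    method: str


def contrast_weight(group: ProbeProfile, baseline: ProbeProfile,
                    method: str = "tfidf-log-ratio") -> ContrastMatrix:
    """Weight group cosines by their distinctiveness from the baseline.

    ``tfidf-log-ratio`` (default): weighted(p) = c_group(p) * log(mean_base /
    c_base(p)) — the group cosine plays term frequency, the log inverse
    relative baseline prevalence plays idf.  A probe as close to the baseline
    as the average probe gets weight 0; closer gets negative weight.
    Baseline scores are floored at 1e-6 before the log.
    ``difference``: c_group(p) - c_base(p).
    """
    if group.probes != baseline.probes:
        raise InvalidInputError("group and baseline probe sets differ")
    keys = tuple(sorted(group.probes))
    g = np.array([group.scores[k] for k in keys])
    b = np.array([baseline.scores[k] for k in keys])
    if method == "tfidf-log-ratio":
        b_floor = np.maximum(b, BASELINE_FLOOR)
        weighted = g * np.log(b_floor.mean() / b_floor)
    elif method == "difference":
        weighted = g - b
    else:
        raise InvalidInputError(f"unknown contrast method {method!r}")
    return ContrastMatrix(probes=keys, group_scores=g, baseline_scores=b,
                          weighted_scores=dict(zip(keys, weighted.tolist())),
                          method=method)


def top_probes(matrix: ContrastMatrix, k: int) -> list[str]:
    """The k probes with the largest positive weighted scores, descending;
    fewer if fewer positives exist.  Ties break lexicographically."""
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    positive = [(p, s) for p, s in matrix.weighted_scores.items() if s > 0]
    positive.sort(key=lambda ps: (-ps[1], ps[0]))
    return [p for p, _ in positive[:k]]


@dataclass(frozen=True)
class ClusterSolution:
    points: dict[str, tuple[float, float]]
    labels: dict[str, int]
    k: int
    silhouette: float


def cluster_probes(probes: Sequence[str], space: EmbeddingSpace,
                   k_range: Sequence[int] = range(2, 11),
                   seed: int = 0,
                   reduction: str = "pca",
                   perplexity: float | None = None) -> ClusterSolution:
    """Cluster probe embeddings in a 2-D reduction with k-means++, choosing
    the k in ``k_range`` that maximises the silhouette coefficient.

    ``reduction`` is ``'pca'`` (deterministic default) or ``'tsne'`` (the
    stochastic-neighbor reduction; ``perplexity`` defaults to
    min(30, (n-1)/3)).  Deterministic for a fixed seed.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    probes = list(probes)
    if len(probes) < 3:
        raise InvalidInputError("need at least 3 probes to cluster")
    k_range = [k for k in k_range if 2 <= k <= len(probes) - 1]
    if not k_range:
        raise InvalidInputError("k_range has no feasible k in [2, n-1]")
    X = space.vectors(probes)
    if reduction == "pca":
        from sklearn.decomposition import PCA
        pts = PCA(n_components=2, random_state=seed).fit_transform(X)
    elif reduction == "tsne":
        from sklearn.manifold import TSNE
        if perplexity is None:
            perplexity = min(30.0, (len(probes) - 1) / 3)
        pts = TSNE(n_components=2, random_state=seed,
                   perplexity=perplexity, init="pca").fit_transform(X)
    else:
        raise InvalidInputError(f"unknown reduction {reduction!r}")
    pts = np.asarray(pts, dtype=float)

    best = None
    for k in k_range:
        km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                    random_state=seed).fit(pts)
        if len(set(km.labels_)) < 2:
            continue
        sil = float(silhouette_score(pts, km.labels_))
        if best is None or sil > best[0]:
            best = (sil, k, km.labels_)
    if best is None:
        raise InvalidInputError("no clustering produced two distinct clusters")
    sil, k, labels = best
    return ClusterSolution(
        points={p: (float(x), float(y)) for p, (x, y) in zip(probes, pts)},
        labels={p: int(l) for p, l in zip(probes, labels)},
        k=k, silhouette=sil)


@dataclass(frozen=True)
class ConceptVector:
    """Unit-normalized sum of a probe cluster's embeddings."""
    member_keys: frozenset[str]
    vector: np.ndarray


def concept_vector(keys: Sequence[str], space: EmbeddingSpace) -> ConceptVector:
    """Sum the member embeddings and normalize by the magnitude."""
    in_vocab = [k for k in keys if k in space]
    if not in_vocab:
        raise InvalidInputError("no concept key found in embedding space")
    vec = unit_normalize(space.vectors(in_vocab).sum(axis=0))
    return ConceptVector(member_keys=frozenset(in_vocab), vector=vec)


def concept_predictor(concept: ConceptVector,
                      sentences: Sequence[SentenceVector]) -> float:
    """Largest cosine between the concept vector and any sentence vector."""
    if not sentences:
        raise InvalidInputError("concept_predictor requires at least one sentence")
    return max(cosine(concept.vector, s.vector) for s in sentences)
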