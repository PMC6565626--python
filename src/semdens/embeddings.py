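"""Word-embedding space: training, persistence, lookup, probe selection.

Keys are POS-prefixed lemmas (``NN_voice``).  The space stores a fixed-
dimension real vector and a corpus token frequency per key, persists in the
standard word2vec text format, and supports frequency-coverage probe
selection ("the words covering 95% of corpus tokens").

Training uses an in-package skip-gram with negative sampling (SGNS)
implemented directly on numpy.  It follows the standard formulation —
maximise log sigma(v_w . v_c) over observed (target, context) pairs within a
symmetric window, minus k sampled negatives drawn from the unigram^0.75
distribution — and is intended for the modest corpora this package trains on;
it is plain stochastic gradient descent with a linearly decaying rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, InvalidInputError


def vector_length(v: np.ndarray) -> float:
    """Euclidean norm (the magnitude of a vector)."""
    return float(np.linalg.norm(np.asarray(v, dtype=float)))


def unit_normalize(v: np.ndarray) -> np.ndarray:
    """Scale a vector to unit norm; direction preserved."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise DegenerateInputError("cannot normalize a zero vector")
    return v / n


@dataclass(frozen=True)
class EmbeddingConfig:
    dimension: int = 200
    window: int = 5
    epochs: int = 4
    algorithm: str = "skip-gram"
    min_count: int = 1
    negative: int = 5
    learning_rate: float = 0.025

    def __post_init__(self):
        for name in ("dimension", "window", "epochs", "min_count"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.algorithm != "skip-gram":
            raise InvalidInputError("only the skip-gram algorithm is supported")


class EmbeddingSpace:
    """Vocabulary of POS-prefixed lemma keys mapped to d-dimensional vectors
    plus a token-frequency table."""

    def __init__(self, keys: Sequence[str], matrix: np.ndarray,
                 frequency: dict[str, int]):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != len(keys):
            raise InvalidInputError("matrix rows must match keys")
        if len(set(keys)) != len(keys):
            raise InvalidInputError("duplicate keys in embedding space")
        for k in keys:
            if frequency.get(k, 0) < 1:
                raise InvalidInputError(f"frequency of {k!r} must be >= 1")
        self.keys = list(keys)
        self.matrix = matrix
        self.frequency = dict(frequency)
        self._index = {k: i for i, k in enumerate(self.keys)}

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def __len__(self) -> int:
        return len(self.keys)

    def vector(self, key: str) -> np.ndarray:
        try:
            return self.matrix[self._index[key]]
        except KeyError:
            raise KeyError(f"{key!r} not in embedding space") from None

    def vectors(self, keys: Sequence[str]) -> np.ndarray:
        return self.matrix[[self._index[k] for k in keys]]

    # -- persistence (word2vec text format) --------------------------------

    def save(self, path: str | Path, precision: int = 8) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.keys)} {self.dimension}\n")
            for k, row in zip(self.keys, self.matrix):
                vals = " ".join(f"{x:.{precision}g}" for x in row)
                fh.write(f"{k} {vals}\n")

    @classmethod
    def load(cls, path: str | Path, frequency: dict[str, int] | None = None
             ) -> "EmbeddingSpace":
        keys, rows = [], []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            n, d = int(header[0]), int(header[1])
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                keys.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        matrix = np.asarray(rows, dtype=float)
        if matrix.shape != (n, d):
            raise InvalidInputError(f"header promises {(n, d)}, file has {matrix.shape}")
        if frequency is None:
            frequency = {k: 1 for k in keys}
        return cls(keys, matrix, frequency)

    def save_frequency(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for k in self.keys:
                fh.write(f"{k}\t{self.frequency[k]}\n")

    @staticmethod
    def load_frequency(path: str | Path) -> dict[str, int]:
        freq = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            k, v = line.split("\t")
            freq[k] = int(v)
        return freq


def probe_vocabulary(space: EmbeddingSpace, coverage: float,
                     mode: str = "coverage") -> list[str]:
    """Most frequent keys, by descending frequency (ties lexicographic).

    ``mode='coverage'`` (default) truncates at the smallest prefix whose
    cumulative token frequency reaches ``coverage`` of total tokens — the
    standard reading of "the 95% most commonly written words as reflected in
    word frequencies".  ``mode='rank'`` instead keeps the top
    ``coverage`` fraction of vocabulary types.
    """
    if not 0 < coverage <= 1:
        raise InvalidInputError("coverage must be in (0, 1]")
    if len(space) == 0:
        raise InvalidInputError("empty embedding space")
    ranked = sorted(space.keys, key=lambda k: (-space.frequency[k], k))
    if mode == "rank":
        n = max(1, math.ceil(coverage * len(ranked)))
        return ranked[:n]
    if mode != "coverage":
        raise InvalidInputError(f"unknown probe selection mode {mode!r}")
    total = sum(space.frequency[k] for k in ranked)
    cum, out = 0, []
    for k in ranked:
        out.append(k)
        cum += space.frequency[k]
        if cum >= coverage * total:
            break
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embeddings(corpus: Iterable[Sequence[str]],
                     config: EmbeddingConfig = EmbeddingConfig(),
                     seed: int = 0) -> EmbeddingSpace:
    """Train skip-gram embeddings with negative sampling on a token stream.

    ``corpus`` is an iterable of sentences, each a sequence of POS-prefixed
    lemma keys.  Every key meeting ``min_count`` receives a vector; the
    frequency table counts all corpus tokens of retained keys.  Deterministic
    for a fixed seed.
    """
    sentences = [list(s) for s in corpus]
    if not sentences or not any(sentences):
        raise InvalidInputError("corpus is empty")

    freq: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            freq[tok] = freq.get(tok, 0) + 1
    keys = sorted(k for k, c in freq.items() if c >= config.min_count)
    if not keys:
        raise InvalidInputError("no token meets min_count")
    index = {k: i for i, k in enumerate(keys)}
    counts = np.array([freq[k] for k in keys], dtype=float)

    rng = np.random.default_rng(seed)
    d = config.dimension
    W = (rng.random((len(keys), d)) - 0.5) / d   # target vectors
    C = np.zeros((len(keys), d))                 # context vectors

    # unigram^0.75 negative-sampling distribution
    neg_p = counts ** 0.75
    neg_p /= neg_p.sum()

    encoded = [[index[t] for t in sent if t in index] for sent in sentences]
    encoded = [s for s in encoded if len(s) >= 2]
    n_pairs_total = sum(len(s) * config.window * 2 for s in encoded) * config.epochs
    pair_i = 0
    for _epoch in range(config.epochs):
        for sent in encoded:
            for pos, wi in enumerate(sent):
                lo = max(0, pos - config.window)
                hi = min(len(sent), pos + config.window + 1)
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    lr = config.learning_rate * max(
                        1e-4, 1.0 - pair_i / max(1, n_pairs_total))
                    pair_i += 1
                    ci = sent[cpos]
                    negs = rng.choice(len(keys), size=config.negative, p=neg_p)
                    ctx_idx = np.concatenate(([ci], negs))
                    labels = np.zeros(len(ctx_idx))
                    labels[0] = 1.0
                    ctx = C[ctx_idx]
                    g = _sigmoid(ctx @ W[wi]) - labels
                    grad_w = g @ ctx
                    C[ctx_idx] -= lr * np.outer(g, W[wi])
                    W[wi] -= lr * grad_w

    return EmbeddingSpace(keys, W, {k: freq[k] for k in keys})
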