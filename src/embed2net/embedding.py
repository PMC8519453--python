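"""Skip-gram word embeddings with negative sampling, plus similarity queries.

The trainer follows the classic word2vec recipe: dynamic context windows
(effective window drawn uniformly from 1..window per center), frequent-word
subsampling, unigram^0.75 negative sampling, and a linearly decaying learning
rate. Updates are applied in small vectorized batches with a seeded numpy
generator, so training is single-threaded and bit-reproducible.

Defaults mirror common biomedical practice: 300 dimensions, window 5,
min_count 5, 5 negatives, 5 epochs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import TokenSequence
from .errors import ParameterError, TermNotFoundError, TrainingError


@dataclass(frozen=True)
class EmbeddingConfig:
    dimension: int = 300
    window: int = 5
    min_count: int = 5
    negative_samples: int = 5
    epochs: int = 5
    seed: int = 0
    deterministic_mode: bool = True
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    subsample: float = 1e-3
    batch_size: int = 1024

    def __post_init__(self):
        if self.dimension < 1 or self.window < 1 or self.min_count < 1:
            raise ParameterError("dimension, window and min_count must be >= 1")


@dataclass(frozen=True)
class NeighborResult:
    term: str
    neighbors: tuple[tuple[str, float], ...]


class Embedding:
    """Vocabulary with one fixed-length vector per term and optional type labels."""

    def __init__(self, vocab: Sequence[str], vectors: np.ndarray,
                 type_labels: Mapping[str, str] | None = None):
        vectors = np.asarray(vectors, dtype=np.float64)
        if len(vocab) != vectors.shape[0]:
            raise ParameterError("vocabulary and vector count differ")
        if not np.all(np.isfinite(vectors)):
            raise ParameterError("vectors must be finite")
        if len(set(vocab)) != len(vocab):
            raise ParameterError("vocabulary terms must be unique")
        self.vocab = list(vocab)
        self.vectors = vectors
        self._index = {t: i for i, t in enumerate(self.vocab)}
        self.type_labels = dict(type_labels or {})
        self._unit: np.ndarray | None = None

    # -- basic queries ----------------------------------------------------
    def __contains__(self, term: str) -> bool:
        return term in self._index

    def __len__(self) -> int:
        return len(self.vocab)

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def vector(self, term: str) -> np.ndarray:
        try:
            return self.vectors[self._index[term]]
        except KeyError:
            raise TermNotFoundError(f"term {term!r} not in vocabulary") from None

    def indices(self, terms: Iterable[str]) -> np.ndarray:
        missing = [t for t in terms if t not in self._index]
        if missing:
            raise TermNotFoundError(f"terms not in vocabulary: {missing[:10]}")
        return np.array([self._index[t] for t in terms], dtype=np.intp)

    def _unit_vectors(self) -> np.ndarray:
        if self._unit is None:
            norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            self._unit = self.vectors / norms
        return self._unit

    def cosine(self, term_a: str, term_b: str) -> float:
        # computed on unit vectors so single and batch queries share one
        # float path (threshold equality must agree bit-for-bit)
        ia, ib = self.indices([term_a, term_b])
        unit = self._unit_vectors()
        return float(np.clip(np.dot(unit[ia], unit[ib]), -1.0, 1.0))

    def pairwise_cosines(self, terms: Sequence[str],
                         chunk: int = 1024) -> np.ndarray:
        """Full cosine matrix for a list of in-vocabulary terms.

        Computed in row chunks; the per-block products are the same calls
        the network builder makes, so thresholding decisions agree
        bit-for-bit between the two.
        """
        unit = self._unit_vectors()[self.indices(terms)]
        blocks = [np.clip(unit[start:start + chunk] @ unit.T, -1.0, 1.0)
                  for start in range(0, len(terms), chunk)]
        return np.vstack(blocks) if blocks else np.empty((0, 0))


def cosine(embedding: Embedding, term_a: str, term_b: str) -> float:
    return embedding.cosine(term_a, term_b)


def nearest_neighbors(embedding: Embedding, term: str, k: int,
                      type_filter: str | None = None) -> NeighborResult:
    """Top-k terms by cosine; ties broken lexicographically; query excluded."""
    if k < 0:
        raise ParameterError("k must be >= 0")
    qi = embedding.indices([term])[0]
    unit = embedding._unit_vectors()
    sims = np.clip(unit @ unit[qi], -1.0, 1.0)
    candidates = []
    for i, other in enumerate(embedding.vocab):
        if i == qi:
            continue
        if type_filter is not None and \
                embedding.type_labels.get(other) != type_filter:
            continue
        candidates.append((other, float(sims[i])))
    candidates.sort(key=lambda ts: (-ts[1], ts[0]))
    return NeighborResult(term, tuple(candidates[:k]))


def neighbor_stability(embeddings: Sequence[Embedding], term: str, k: int
                       ) -> tuple[set[str], pd.DataFrame]:
    """Neighbors of `term` common to every embedding's top-k, with a cosine
    trajectory table ordered by descending similarity in the first embedding."""
    if len(embeddings) < 2:
        raise ParameterError("need at least two embeddings")
    for j, emb in enumerate(embeddings):
        if term not in emb:
            raise TermNotFoundError(f"term {term!r} missing from embedding {j}")
    top_sets = [set(t for t, _ in nearest_neighbors(e, term, k).neighbors)
                for e in embeddings]
    common = set.intersection(*top_sets)
    order = sorted(common, key=lambda t: (-embeddings[0].cosine(term, t), t))
    table = pd.DataFrame(
        {f"embedding_{j}": [emb.cosine(term, t) for t in order]
         for j, emb in enumerate(embeddings)},
        index=pd.Index(order, name="neighbor"))
    return common, table


# -- training -------------------------------------------------------------

def _scatter_add(W: np.ndarray, idx: np.ndarray, G: np.ndarray) -> None:
    """W[idx] += G with duplicate indices accumulated (fast np.add.at)."""
    order = np.argsort(idx, kind="stable")
    idx_sorted = idx[order]
    boundaries = np.flatnonzero(np.diff(idx_sorted)) + 1
    starts = np.concatenate(([0], boundaries))
    sums = np.add.reduceat(G[order], starts, axis=0)
    W[idx_sorted[starts]] += sums


def _skipgram_pairs(ids: np.ndarray, window: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Dynamic-window (center, context) pairs for one document."""
    n = len(ids)
    b = rng.integers(1, window + 1, size=n)
    centers, contexts = [], []
    for s in range(1, window + 1):
        if s >= n:
            break
        # context s positions to the left / right of the center
        left = b[s:] >= s
        centers.append(ids[s:][left]);  contexts.append(ids[:-s][left])
        right = b[:-s] >= s
        centers.append(ids[:-s][right]); contexts.append(ids[s:][right])
    if not centers:
        return (np.empty(0, np.int32),) * 2
    return np.concatenate(centers), np.concatenate(contexts)


def train_embedding(corpus: Iterable[TokenSequence | Sequence[str]],
                    config: EmbeddingConfig = EmbeddingConfig(),
                    type_labels: Mapping[str, str] | None = None) -> Embedding:
    """Train skip-gram negative-sampling vectors on a tokenized corpus.

    The vocabulary is exactly the set of tokens with corpus frequency >=
    min_count. Raises TrainingError on an empty corpus or empty vocabulary.
    """
    docs = [tuple(seq.tokens) if isinstance(seq, TokenSequence) else tuple(seq)
            for seq in corpus]
    if not docs or all(len(d) == 0 for d in docs):
        raise TrainingError("empty corpus")
    counts = Counter(tok for d in docs for tok in d)
    vocab = sorted((w for w, c in counts.items() if c >= config.min_count),
                   key=lambda w: (-counts[w], w))
    if not vocab:
        raise TrainingError(
            f"no token reaches min_count={config.min_count}")
    index = {w: i for i, w in enumerate(vocab)}
    id_docs = [np.array([index[t] for t in d if t in index], dtype=np.int32)
               for d in docs]
    id_docs = [d for d in id_docs if len(d) >= 2]
    if not id_docs:
        raise TrainingError("no document retains >= 2 in-vocabulary tokens")

    freqs = np.array([counts[w] for w in vocab], dtype=np.float64)
    rel = freqs / freqs.sum()
    if config.subsample > 0:
        keep = np.minimum(
            1.0, np.sqrt(config.subsample / rel) + config.subsample / rel)
    else:
        keep = np.ones_like(rel)
    noise = freqs ** 0.75
    noise_cdf = np.cumsum(noise / noise.sum())

    rng = np.random.default_rng(config.seed)
    dim = config.dimension
    w_in = (rng.random((len(vocab), dim)) - 0.5) / dim
    w_out = np.zeros((len(vocab), dim))

    # rough pair budget for the linear learning-rate decay
    total_tokens = sum(len(d) for d in id_docs)
    est_total = max(1, int(total_tokens * (config.window + 1) *
                           config.epochs))
    processed = 0
    labels = np.zeros(config.negative_samples + 1)
    labels[0] = 1.0

    for _epoch in range(config.epochs):
        cs, os_ = [], []
        for ids in id_docs:
            if config.subsample > 0:
                ids = ids[rng.random(len(ids)) < keep[ids]]
            if len(ids) < 2:
                continue
            c, o = _skipgram_pairs(ids, config.window, rng)
            cs.append(c); os_.append(o)
        if not cs:
            continue
        centers = np.concatenate(cs)
        contexts = np.concatenate(os_)
        perm = rng.permutation(len(centers))
        centers, contexts = centers[perm], contexts[perm]
        for start in range(0, len(centers), config.batch_size):
            c = centers[start:start + config.batch_size]
            o = contexts[start:start + config.batch_size]
            bsz = len(c)
            neg = np.searchsorted(
                noise_cdf, rng.random((bsz, config.negative_samples))
            ).astype(np.int32)
            targets = np.concatenate([o[:, None], neg], axis=1)
            lr = max(config.min_learning_rate,
                     config.learning_rate * (1 - processed / est_total))
            u = w_in[c]                       # (B, d)
            v = w_out[targets]                # (B, 1+neg, d)
            score = 1.0 / (1.0 + np.exp(-np.einsum("bd,bkd->bk", u, v)))
            g = (labels[None, :] - score) * lr
            grad_u = np.einsum("bk,bkd->bd", g, v)
            grad_v = g[:, :, None] * u[:, None, :]
            _scatter_add(w_in, c.astype(np.int64), grad_u)
            _scatter_add(w_out, targets.ravel().astype(np.int64),
                         grad_v.reshape(-1, dim))
            processed += bsz

    kept_types = None
    if type_labels is not None:
        kept_types = {t: ty for t, ty in type_labels.items() if t in index}
    return Embedding(vocab, w_in, kept_types)


# -- persistence (word2vec text format) -----------------------------------

def save_embedding(embedding: Embedding, path: str | Path,
                   types_path: str | Path | None = None) -> None:
    """Write word2vec text format: header "<vocab> <dim>", then term + vector."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(embedding)} {embedding.dimension}\n")
        for term, vec in zip(embedding.vocab, embedding.vectors):
            fh.write(term + " " + " ".join(repr(float(x)) for x in vec) + "\n")
    if types_path is not None and embedding.type_labels:
        with open(types_path, "w", encoding="utf-8") as fh:
            for term, etype in embedding.type_labels.items():
                fh.write(f"{term}\t{etype}\n")


def load_embedding(path: str | Path,
                   types_path: str | Path | None = None) -> Embedding:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParameterError(f"malformed word2vec header in {path}")
        n, dim = int(header[0]), int(header[1])
        vocab, rows = [], np.empty((n, dim))
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            vocab.append(parts[0])
            rows[i] = [float(x) for x in parts[1:dim + 1]]
    type_labels = None
    if types_path is not None and Path(types_path).exists():
        type_labels = {}
        with open(types_path, encoding="utf-8") as fh:
            for line in fh:
                term, _, etype = line.rstrip("\n").partition("\t")
                type_labels[term] = etype
    return Embedding(vocab, rows, type_labels)
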