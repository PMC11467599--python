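"""Word embeddings with character n-gram inference for unseen tokens.

The trainer is skip-gram with negative sampling, run in seeded mini-batches
so that training is fully deterministic on a single CPU. After training,
character n-gram (3-5 gram) vectors are induced as the mean of the vectors
of the vocabulary words containing each n-gram; an out-of-vocabulary token
(a typo such as "burnnt") is then embedded as the mean of its known n-gram
vectors. This gives the subword robustness that informal social-media
spelling requires while keeping the trainer self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def _char_ngrams(word: str, min_n: int = 3, max_n: int = 5) -> list[str]:
    w = f"<{word}>"
    grams = []
    for n in range(min_n, max_n + 1):
        grams.extend(w[i:i + n] for i in range(len(w) - n + 1))
    return grams


@dataclass
class EmbeddingModel:
    """Vocabulary embeddings plus optional subword inference.

    Similarity is cosine throughout; all scores are invariant to positive
    rescaling of the vectors.
    """

    dim: int
    vocab: list[str]
    vectors: np.ndarray  # (V, dim)
    counts: np.ndarray | None = None
    subword: bool = True
    min_n: int = 3
    max_n: int = 5
    metadata: dict = field(default_factory=dict)
    _index: dict = field(default_factory=dict, repr=False)
    _ngram_vecs: dict = field(default_factory=dict, repr=False)
    _unit: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")
        self._index = {w: i for i, w in enumerate(self.vocab)}
        if self.subword:
            self._build_ngram_table()

    def _build_ngram_table(self) -> None:
        sums: dict[str, np.ndarray] = {}
        ns: dict[str, int] = {}
        for w, vec in zip(self.vocab, self.vectors):
            for g in _char_ngrams(w, self.min_n, self.max_n):
                if g in sums:
                    sums[g] += vec
                    ns[g] += 1
                else:
                    sums[g] = vec.copy()
                    ns[g] = 1
        self._ngram_vecs = {g: sums[g] / ns[g] for g in sums}

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def vector(self, token: str) -> np.ndarray | None:
        """Vector for a token, via subword inference when out of vocabulary.

        Returns None when the token is unknown and no n-gram is known
        (or subword inference is disabled).
        """
        i = self._index.get(token)
        if i is not None:
            return self.vectors[i]
        if not self.subword or not token:
            return None
        grams = [g for g in _char_ngrams(token, self.min_n, self.max_n)
                 if g in self._ngram_vecs]
        if not grams:
            return None
        return np.mean([self._ngram_vecs[g] for g in grams], axis=0)

    def unit_vectors(self) -> np.ndarray:
        """Row-normalized vocabulary matrix (cached)."""
        if self._unit is None:
            norms = np.linalg.norm(self.vectors, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            self._unit = self.vectors / norms
        return self._unit

    def cosine(self, a: str, b: str) -> float:
        va, vb = self.vector(a), self.vector(b)
        if va is None or vb is None:
            raise KeyError(f"no vector for {a if va is None else b!r}")
        return float(cosine(va, vb))

    # -- persistence (word2vec text format) --------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocab)} {self.dim}\n")
            for w, vec in zip(self.vocab, self.vectors):
                fh.write(w + " " + " ".join(repr(float(x)) for x in vec) + "\n")

    @classmethod
    def load(cls, path: str | Path, subword: bool = True) -> "EmbeddingModel":
        with Path(path).open("r", encoding="utf-8") as fh:
            header = fh.readline().split()
            v, d = int(header[0]), int(header[1])
            vocab, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vocab.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(vocab) != v:
            raise ValueError("corrupt embedding file")
        return cls(dim=d, vocab=vocab, vectors=np.asarray(rows), subword=subword)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def train_embeddings(corpus: list[list[str]] | list, dim: int = 50,
                     window: int = 5, epochs: int = 5, seed: int = 0,
                     min_count: int = 2, negative: int = 5,
                     learning_rate: float = 0.05, batch_size: int = 256,
                     subword: bool = True) -> EmbeddingModel:
    """Train skip-gram negative-sampling embeddings on a token corpus.

    Deterministic for a fixed seed: vocabulary order, pair shuffling and
    negative sampling all derive from one seeded generator, and updates are
    applied in seeded mini-batches. Every token with count >= ``min_count``
    enters the vocabulary.
    """
    sentences = [list(s) for s in corpus]
    if not sentences or all(not s for s in sentences):
        raise ValueError("empty corpus")

    counts: dict[str, int] = {}
    for s in sentences:
        for t in s:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted((w for w, c in counts.items() if c >= min_count),
                   key=lambda w: (-counts[w], w))
    if not vocab:
        raise ValueError(f"no token reaches min_count={min_count}")
    index = {w: i for i, w in enumerate(vocab)}
    vcounts = np.array([counts[w] for w in vocab], dtype=np.float64)

    # skip-gram training pairs
    centers, contexts = [], []
    for s in sentences:
        ids = [index[t] for t in s if t in index]
        for i, c in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    centers = np.asarray(centers, dtype=np.int64)
    contexts = np.asarray(contexts, dtype=np.int64)

    rng = np.random.default_rng(seed)
    V = len(vocab)
    W = (rng.random((V, dim)) - 0.5) / dim
    C = np.zeros((V, dim))

    n_pairs = len(centers)
    if n_pairs:
        noise = vcounts ** 0.75
        noise_cdf = np.cumsum(noise / noise.sum())
        n_batches = max(1, -(-n_pairs // batch_size))
        total_steps = epochs * n_batches
        step = 0
        for _ in range(epochs):
            perm = rng.permutation(n_pairs)
            for b in range(n_batches):
                sl = perm[b * batch_size:(b + 1) * batch_size]
                if sl.size == 0:
                    continue
                lr = learning_rate * max(1e-4, 1.0 - step / total_steps)
                step += 1
                ci, oi = centers[sl], contexts[sl]
                neg = np.searchsorted(
                    noise_cdf, rng.random((sl.size, negative)))
                w = W[ci]
                cpos = C[oi]
                g_pos = (1.0 - _sigmoid(np.einsum("bd,bd->b", w, cpos))) * lr
                grad_w = g_pos[:, None] * cpos
                grad_cpos = g_pos[:, None] * w
                cneg = C[neg]
                g_neg = -_sigmoid(np.einsum("bd,bkd->bk", w, cneg)) * lr
                grad_w += np.einsum("bk,bkd->bd", g_neg, cneg)
                grad_cneg = g_neg[:, :, None] * w[:, None, :]
                np.add.at(W, ci, grad_w)
                np.add.at(C, oi, grad_cpos)
                np.add.at(C, neg.ravel(), grad_cneg.reshape(-1, dim))

    return EmbeddingModel(
        dim=dim, vocab=vocab, vectors=W, counts=vcounts, subword=subword,
        metadata={"window": window, "epochs": epochs, "seed": seed,
                  "min_count": min_count, "negative": negative,
                  "learning_rate": learning_rate, "n_pairs": int(n_pairs)})
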