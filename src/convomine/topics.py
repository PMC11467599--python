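"""Fixed-K topic modeling of conversation corpora with multi-topic membership.

Latent Dirichlet allocation with symmetric priors (doc-topic prior 1/K,
topic-word prior 0.01) fitted by batch variational inference, so a fixed
seed reproduces the model exactly. K defaults to 11. Documents are whole
threads on forums and individual tweets/comments elsewhere. Unlike hard
clustering, a document may belong to several topics: it is assigned every
topic whose posterior weight reaches the membership threshold (default
0.25), or its argmax topic when none does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

DEFAULT_K = 11
DEFAULT_TAU = 0.25


@dataclass
class TopicModel:
    K: int
    vocab: list[str]
    topic_word: np.ndarray  # (K, V), rows sum to 1
    doc_topic: np.ndarray   # (N, K), rows sum to 1
    doc_ids: list[str]
    seed: int
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        self._doc_index = {d: i for i, d in enumerate(self.doc_ids)}

    def doc_distribution(self, doc_id: str) -> np.ndarray:
        i = self._doc_index.get(doc_id)
        if i is None:
            raise KeyError(f"unknown document {doc_id!r}")
        return self.doc_topic[i]

    # -- persistence (JSON, for small fixture-sized models) ----------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {"K": self.K, "vocab": self.vocab,
                   "topic_word": self.topic_word.tolist(),
                   "doc_topic": self.doc_topic.tolist(),
                   "doc_ids": self.doc_ids, "seed": self.seed,
                   "hyperparameters": self.hyperparameters}
        path.write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TopicModel":
        d = json.loads(Path(path).read_text())
        return cls(K=d["K"], vocab=d["vocab"],
                   topic_word=np.asarray(d["topic_word"]),
                   doc_topic=np.asarray(d["doc_topic"]),
                   doc_ids=d["doc_ids"], seed=d["seed"],
                   hyperparameters=d.get("hyperparameters", {}))


def _count_matrix(docs: list[list[str]]) -> tuple[sparse.csr_matrix, list[str]]:
    vocab = sorted({t for d in docs for t in d})
    index = {w: i for i, w in enumerate(vocab)}
    rows, cols, vals = [], [], []
    for i, d in enumerate(docs):
        counts: dict[int, int] = {}
        for t in d:
            j = index[t]
            counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    X = sparse.csr_matrix((vals, (rows, cols)),
                          shape=(len(docs), len(vocab)), dtype=np.float64)
    return X, vocab


def fit_topics(docs: list[list[str]] | list, K: int = DEFAULT_K,
               alpha: float | None = None, beta: float = 0.01,
               seed: int = 0, max_iter: int = 50,
               doc_ids: list[str] | None = None) -> TopicModel:
    """Fit a K-topic LDA model to tokenized documents.

    Deterministic under a fixed seed (batch inference, single worker).
    ``alpha`` defaults to the symmetric 1/K prior.
    """
    docs = [list(d) for d in docs]
    if not docs:
        raise ValueError("no documents")
    if K < 1:
        raise ValueError("K must be >= 1")
    X, vocab = _count_matrix(docs)
    if not vocab:
        raise ValueError("empty vocabulary")
    if alpha is None:
        alpha = 1.0 / K
    lda = LatentDirichletAllocation(
        n_components=K, doc_topic_prior=alpha, topic_word_prior=beta,
        learning_method="batch", max_iter=max_iter, random_state=seed,
        n_jobs=1)
    doc_topic = lda.fit_transform(X)
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    # documents with no tokens get the uniform prior back; renormalize defensively
    doc_topic = doc_topic / doc_topic.sum(axis=1, keepdims=True)
    if doc_ids is None:
        doc_ids = [str(i) for i in range(len(docs))]
    return TopicModel(K=K, vocab=vocab, topic_word=topic_word,
                      doc_topic=doc_topic, doc_ids=list(doc_ids), seed=seed,
                      hyperparameters={"alpha": alpha, "beta": beta,
                                       "max_iter": max_iter})


# --- assignment and overlap --------------------------------------------------

def assign_topics(model: TopicModel, doc_id: str,
                  tau: float = DEFAULT_TAU) -> set[int]:
    """Topics whose weight reaches tau; the argmax topic(s) if none does."""
    dist = model.doc_distribution(doc_id)
    chosen = {int(k) for k in np.flatnonzero(dist >= tau)}
    if not chosen:
        top = dist.max()
        chosen = {int(k) for k in np.flatnonzero(dist == top)}
    return chosen


@dataclass
class TopicAssignment:
    doc_topics: dict[str, set[int]]
    tau: float

    def docs_in(self, topic: int) -> set[str]:
        return {d for d, ts in self.doc_topics.items() if topic in ts}


def assign_all(model: TopicModel, tau: float = DEFAULT_TAU) -> TopicAssignment:
    return TopicAssignment(
        doc_topics={d: assign_topics(model, d, tau) for d in model.doc_ids},
        tau=tau)


def top_words(model: TopicModel, topic: int, n: int = 20) -> list[str]:
    """The n highest-probability terms of a topic, ties lexicographic."""
    if not 0 <= topic < model.K:
        raise IndexError(f"topic {topic} out of range for K={model.K}")
    probs = model.topic_word[topic]
    ranked = sorted(zip(-probs, model.vocab))
    return [w for _, w in ranked[:n]]


def overlap(assignment: TopicAssignment, a: int, b: int,
            total: int) -> tuple[int, float]:
    """Documents assigned to both topics: (count, percentage to 1 dp)."""
    from .characterize import pct
    if a == b:
        raise ValueError("overlap requires two distinct topics")
    count = len(assignment.docs_in(a) & assignment.docs_in(b))
    return count, (pct(count, total, 1) if total else 0.0)


def multi_topic_rate(assignment: TopicAssignment, total: int) -> float:
    """Percentage of documents assigned to two or more topics (2 dp)."""
    from .characterize import pct
    if total == 0:
        return 0.0
    n_multi = sum(1 for ts in assignment.doc_topics.values() if len(ts) >= 2)
    return pct(n_multi, total, 2)


def overlap_matrix(assignment: TopicAssignment, K: int,
                   total: int) -> np.ndarray:
    """Pairwise co-assignment counts (diagonal: per-topic totals)."""
    m = np.zeros((K, K), dtype=int)
    for ts in assignment.doc_topics.values():
        for a in ts:
            for b in ts:
                m[a, b] += 1
    return m
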