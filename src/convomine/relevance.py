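"""Dual-lexicon relevance filtering in embedding space.

A positive seed lexicon (the burn and first-aid search terms) and a negative
seed lexicon (exclusion-sense terms: calories, energy, bridges, ...) are each
expanded with their k nearest vocabulary neighbours. Every analysis unit is
scored by the mean cosine similarity between its tokens and each expanded
lexicon, and classified relevant when it scores high against the positive
lexicon AND low against the negative one — two thresholds, set empirically
per platform by grid calibration against labelled examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddingModel
from .io import Thread
from .lexicon import PlatformProfile, SearchTaxonomy
from .preprocess import DEFAULT_STOPWORDS, lemmatize, tokenize_lemmatize


@dataclass(frozen=True)
class ExpandedLexicon:
    polarity: str  # "relevant" | "irrelevant"
    seed_terms: tuple[str, ...]
    neighbor_terms: tuple[str, ...]

    @property
    def combined(self) -> tuple[str, ...]:
        return self.seed_terms + self.neighbor_terms


@dataclass(frozen=True)
class RelevanceScore:
    pos_mean: float
    neg_mean: float
    n_tokens: int

    @property
    def defined(self) -> bool:
        return self.n_tokens > 0


@dataclass(frozen=True)
class ThresholdPair:
    platform: str
    theta_pos: float
    theta_neg: float
    provenance: dict = field(default_factory=dict, hash=False, compare=False)


@dataclass
class FilterReport:
    platform: str
    analysis_unit: str
    n_before: int
    n_after: int

    @property
    def reduction_pct(self) -> float:
        from .characterize import pct
        if self.n_before == 0:
            return 0.0
        return pct(self.n_before - self.n_after, self.n_before, 0)

    def to_dict(self) -> dict:
        return {"platform": self.platform, "analysis_unit": self.analysis_unit,
                "n_before": self.n_before, "n_after": self.n_after,
                "reduction_pct": self.reduction_pct}


# --- seed construction -------------------------------------------------------

def _seed_tokens(terms, stopwords=DEFAULT_STOPWORDS) -> tuple[str, ...]:
    """Lemma-level seed tokens from taxonomy terms; multiword terms
    contribute each non-stopword token."""
    out: list[str] = []
    for term in terms:
        for tok in term.split():
            lem = lemmatize(tok)
            if lem and lem not in stopwords and lem not in out:
                out.append(lem)
    return tuple(out)


def positive_seed_terms(taxonomy: SearchTaxonomy) -> tuple[str, ...]:
    terms = (taxonomy.terms("burn_injury") + taxonomy.terms("fa_general")
             + taxonomy.terms("fa_specific") + taxonomy.terms("fa_food"))
    return _seed_tokens(terms)


def negative_seed_terms(taxonomy: SearchTaxonomy) -> tuple[str, ...]:
    return _seed_tokens(taxonomy.terms("exclusion"))


# --- lexicon expansion -------------------------------------------------------

def _neighbor_sims(model: EmbeddingModel, seed_vecs: np.ndarray,
                   mode: str) -> np.ndarray:
    unit = model.unit_vectors()
    norms = np.linalg.norm(seed_vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    seed_unit = seed_vecs / norms
    sims = unit @ seed_unit.T  # (V, S)
    if mode == "max":
        return sims.max(axis=1)
    if mode == "centroid":
        centroid = seed_unit.mean(axis=0)
        n = np.linalg.norm(centroid)
        return unit @ (centroid / n if n else centroid)
    raise ValueError(f"unknown aggregation mode {mode!r}")


def expand_lexicon(model: EmbeddingModel, seeds, k: int,
                   polarity: str, mode: str = "max",
                   negate: bool = False) -> ExpandedLexicon:
    """Augment seeds with the k nearest vocabulary terms.

    Neighbour affinity is the maximum cosine to any seed (or to the seed
    centroid with ``mode="centroid"``); ties break lexicographically.
    With ``negate=True`` the seed vectors are sign-flipped first — the
    alternative construction of an irrelevant-sense lexicon from the
    antipodes of the positive seeds.
    """
    seeds = tuple(seeds)
    if k < 0:
        raise ValueError("k must be nonnegative")
    vecs = [(s, model.vector(s)) for s in seeds]
    seed_vecs = np.array([v for _, v in vecs if v is not None])
    if seed_vecs.size == 0:
        raise ValueError("no seed term has a vector")
    if negate:
        seed_vecs = -seed_vecs
    if k == 0:
        return ExpandedLexicon(polarity, seeds, ())
    sims = _neighbor_sims(model, seed_vecs, mode)
    seed_set = set(seeds)
    ranked = sorted(
        ((-sims[i], w) for i, w in enumerate(model.vocab) if w not in seed_set))
    neighbors = tuple(w for _, w in ranked[:k])
    return ExpandedLexicon(polarity, seeds, neighbors)


# --- scoring and classification ----------------------------------------------

def _unit_rows(vecs: list[np.ndarray]) -> np.ndarray:
    m = np.asarray(vecs, dtype=float)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return m / norms


def _lexicon_matrix(lex: ExpandedLexicon, model: EmbeddingModel) -> np.ndarray:
    vecs = [v for v in (model.vector(t) for t in lex.combined) if v is not None]
    if not vecs:
        raise ValueError(f"no {lex.polarity!r} lexicon term has a vector")
    return _unit_rows(vecs)


def score_unit(tokens, pos: ExpandedLexicon, neg: ExpandedLexicon,
               model: EmbeddingModel) -> RelevanceScore:
    """Mean pairwise cosine between a unit's tokens and each lexicon.

    Tokens without a vector (subword inference off and out of vocabulary)
    are skipped and excluded from ``n_tokens``; a unit with no scorable
    token yields an undefined score.
    """
    pos_m = _lexicon_matrix(pos, model)
    neg_m = _lexicon_matrix(neg, model)
    vecs = [v for v in (model.vector(t) for t in tokens) if v is not None]
    if not vecs:
        return RelevanceScore(0.0, 0.0, 0)
    tok_m = _unit_rows(vecs)
    return RelevanceScore(
        pos_mean=float((tok_m @ pos_m.T).mean()),
        neg_mean=float((tok_m @ neg_m.T).mean()),
        n_tokens=len(vecs))


def classify(score: RelevanceScore, thresholds: ThresholdPair) -> str:
    """"relevant" iff pos_mean >= theta_pos and neg_mean <= theta_neg
    (both boundaries inclusive)."""
    if not score.defined:
        raise ValueError("cannot classify an undefined score")
    ok = (score.pos_mean >= thresholds.theta_pos
          and score.neg_mean <= thresholds.theta_neg)
    return "relevant" if ok else "irrelevant"


# --- threshold calibration ---------------------------------------------------

def _f1(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray) -> np.ndarray:
    denom = 2 * tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(denom > 0, 2 * tp / denom, 0.0)
    return f1


def _candidates(values: np.ndarray, grid: int) -> np.ndarray:
    uniq = np.unique(values)
    if len(uniq) <= grid:
        return uniq
    qs = np.linspace(0, 1, grid)
    return np.unique(np.quantile(uniq, qs, method="nearest"))


def calibrate_thresholds(scored, objective: str = "f1", grid: int = 128,
                         platform: str = "") -> ThresholdPair:
    """Grid-search the (theta_pos, theta_neg) pair maximizing the objective
    (F1 on the relevant class by default) against gold labels.

    Candidate thresholds are the observed score values (quantile-thinned to
    ``grid`` points when there are more). Ties break deterministically:
    smallest theta_pos, then largest theta_neg. Units with undefined scores
    are always classified irrelevant and enter the tally as such.
    """
    labels = np.array([bool(y) for _, y in scored])
    if labels.all() or not labels.any():
        raise ValueError("calibration sample must contain both classes")
    defined = np.array([s.defined for s, _ in scored])
    pos = np.array([s.pos_mean for s, _ in scored])[defined]
    neg = np.array([s.neg_mean for s, _ in scored])[defined]
    y = labels[defined]
    fn_fixed = int(labels[~defined].sum())  # undefined golds count as misses

    theta_ps = _candidates(pos, grid)
    theta_ns = _candidates(neg, grid)[::-1]  # descending for tie-break
    best = None
    for tp_ in theta_ps:
        mp = pos >= tp_
        pred = mp[None, :] & (neg[None, :] <= theta_ns[:, None])  # (N, n)
        tp = (pred & y[None, :]).sum(axis=1).astype(float)
        fp = (pred & ~y[None, :]).sum(axis=1).astype(float)
        fn = ((~pred) & y[None, :]).sum(axis=1).astype(float) + fn_fixed
        if objective == "f1":
            obj = _f1(tp, fp, fn)
        elif objective == "accuracy":
            tn = ((~pred) & ~y[None, :]).sum(axis=1) + (~labels[~defined]).sum()
            obj = (tp + tn) / len(labels)
        else:
            raise ValueError(f"unknown objective {objective!r}")
        j = int(np.argmax(obj))  # first (= largest theta_neg) among ties
        if best is None or obj[j] > best[0] + 1e-15:
            best = (float(obj[j]), float(tp_), float(theta_ns[j]))
    score, theta_pos, theta_neg = best
    return ThresholdPair(platform=platform, theta_pos=theta_pos,
                         theta_neg=theta_neg,
                         provenance={"objective": objective,
                                     "objective_value": score,
                                     "grid": grid, "n": len(scored)})


# --- corpus filtering --------------------------------------------------------

def _classify_text(text: str, pos, neg, model, thresholds, stopwords) -> bool:
    tokens = tokenize_lemmatize(text, stopwords)
    score = score_unit(tokens, pos, neg, model)
    if not score.defined:
        return False  # conservative: nothing scorable -> irrelevant
    return classify(score, thresholds) == "relevant"


def filter_corpus(threads: list[Thread], profile: PlatformProfile,
                  pos: ExpandedLexicon, neg: ExpandedLexicon,
                  model: EmbeddingModel, thresholds: ThresholdPair,
                  stopwords=None) -> tuple[list[Thread], FilterReport]:
    """Classify each analysis unit and retain the relevant content.

    Forums score the title-plus-main-post and keep or drop whole threads;
    tweet and comment platforms score each post and keep the relevant ones.
    """
    if stopwords is None:
        stopwords = DEFAULT_STOPWORDS
    retained: list[Thread] = []
    if profile.analysis_unit == "title_plus_main_post":
        before = len(threads)
        for t in threads:
            if _classify_text(t.main_unit_text(), pos, neg, model,
                              thresholds, stopwords):
                retained.append(t)
        after = len(retained)
    else:
        before = after = 0
        for t in threads:
            keep = [p for p in t.posts
                    if _classify_text(p.text, pos, neg, model,
                                      thresholds, stopwords)]
            before += len(t.posts)
            after += len(keep)
            if keep:
                retained.append(Thread(id=t.id, platform=t.platform,
                                       posts=keep, title=t.title))
    report = FilterReport(platform=profile.platform,
                          analysis_unit=profile.analysis_unit,
                          n_before=before, n_after=after)
    return retained, report
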