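"""Seeded synthetic conversation corpora with gold labels.

Emulates the statistical structure the pipeline assumes: multi-post threads
of variable length and user count; posts that use burn terms in the injury
sense versus distractor senses ("burn calories", "burnout", "burn bridges");
emoji/punctuation noise and occasional misspellings; timestamps across
calendar years with configurable yearly intensity; user descriptions that
carry parent terms at a configurable rate; and per-unit gold labels for
relevance, purpose, burn type and injured party.

Post text is template-based with slot-filled filler words: controllable
gold labels matter more than linguistic realism here. Every post labelled
relevant contains at least one burn term and one first-aid term by
construction, so the query matcher can assert label consistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .characterize import PURPOSES, BURN_TYPES, INJURED_PARTIES, BurnRecord
from .io import Post, Thread
from .lexicon import SearchTaxonomy, default_taxonomy
from .preprocess import tokenize_lemmatize


# --- configuration ------------------------------------------------------------

@dataclass(frozen=True)
class PlatformSpec:
    platform: str
    kind: str  # "forum" | "microblog" | "video_comments"
    n_threads: int
    # shifted negative binomial for replies: n_posts = 1 + NB(nb_n, nb_p);
    # forums are heavy-tailed (threads from 1 to a few hundred posts)
    nb_n: float = 0.55
    nb_p: float = 0.035

    def __post_init__(self):
        if self.kind not in ("forum", "microblog", "video_comments"):
            raise ValueError(f"unknown platform kind {self.kind!r}")
        if self.n_threads < 0:
            raise ValueError("n_threads must be nonnegative")


DEFAULT_PLATFORMS = (
    PlatformSpec("forum", "forum", n_threads=150),
    PlatformSpec("microblog", "microblog", n_threads=400, nb_n=0.2, nb_p=0.5),
    PlatformSpec("video_comments", "video_comments", n_threads=60,
                 nb_n=1.0, nb_p=0.08),
)


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    platforms: tuple[PlatformSpec, ...] = DEFAULT_PLATFORMS
    relevant_fraction: float = 0.3
    distractor_fraction: float = 0.4  # of irrelevant posts
    year_range: tuple[int, int] = (2004, 2020)
    year_weights: tuple[float, ...] | None = None  # default: linear growth
    parent_term_rate: float = 0.06
    emoji_noise_rate: float = 0.2
    misspell_rate: float = 0.1

    def __post_init__(self):
        for name in ("relevant_fraction", "distractor_fraction",
                     "parent_term_rate", "emoji_noise_rate", "misspell_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        y0, y1 = self.year_range
        if y1 < y0:
            raise ValueError("year_range must be increasing")
        if self.year_weights is not None:
            w = np.asarray(self.year_weights, dtype=float)
            if len(w) != y1 - y0 + 1 or (w < 0).any() or w.sum() <= 0:
                raise ValueError("year_weights must be nonnegative, one per "
                                 "year, with positive sum")

    def years_and_weights(self) -> tuple[np.ndarray, np.ndarray]:
        y0, y1 = self.year_range
        years = np.arange(y0, y1 + 1)
        if self.year_weights is not None:
            w = np.asarray(self.year_weights, dtype=float)
        else:
            w = np.linspace(1.0, 4.0, len(years))  # steady growth
        return years, w / w.sum()


@dataclass
class GoldLabels:
    post_relevance: dict = field(default_factory=dict)   # (thread, post) -> bool
    thread_purpose: dict = field(default_factory=dict)   # thread -> purpose
    burn_records: dict = field(default_factory=dict)     # thread -> BurnRecord
    user_parent: dict = field(default_factory=dict)      # user -> bool
    user_description: dict = field(default_factory=dict) # user -> text

    def relevant_post_ids(self) -> set:
        return {k for k, v in self.post_relevance.items() if v}


# --- text templates -----------------------------------------------------------

_HOT_THINGS = ("oven", "kettle", "iron", "stove", "radiator", "pan",
               "hair straighteners", "bbq", "hot tea", "boiling pot")

_REL_SEEKING = (
    "my {child} just got a {burn} from the {hot} what {fa} should i use",
    "{burn} on my arm from the {hot} this morning would {fa} help at all",
    "little {child} {burn} her hand on the {hot} i held it under cool running {fa} for twenty minutes",
    "bad {burn} blister on his wrist tried {fa} but the skin is still sore any tips",
    "help please {child} touched the {hot} and got {burn} is {fa} safe on broken skin",
)
_REL_OFFERING = (
    "if you get a {burn} from the {hot} cool it with {fa} then cover with a clean dressing",
    "tip for any {burn} never pop the blister just apply {fa} and see a pharmacist",
    "our first aid video shows how to {fa} a {burn} properly keep it cool for twenty minutes",
    "nurse here for a {burn} skip the folk remedies plain {fa} and a loose dressing work",
)
_REL_EXPERIENCE = (
    "last summer i got an awful {burn} at the beach {fa} was the only thing that soothed the skin",
    "when my {child} was small she had a {burn} from the {hot} we used {fa} and it healed well",
)
_REL_NEWS = (
    "new campaign reminds families to treat a {burn} with cool running {fa} for twenty minutes",
    "local clinic reports more {burn} cases this week urging {fa} first aid awareness",
)

_REL_BY_PURPOSE = {
    "seeking_advice": _REL_SEEKING,
    "offering_advice": _REL_OFFERING,
    "experience_sharing": _REL_EXPERIENCE,
    "news": _REL_NEWS,
}

_DISTRACTOR = (
    "trying to {burnword} calories at the gym every single day this week",
    "total burnout at work lately no energy left for anything",
    "never {burnword} bridges with old colleagues you may need them later",
    "this spin class will {burnword} so much energy my legs ache",
    "heartburn again after that spicy curry should stop eating so late",
    "they {burnword} the villain in that film such a savage insult",
    "new diet plan says i {burnword} more calories walking than jogging",
)

_NEUTRAL = (
    "anyone know a reliable plumber near the school",
    "what time does the fair start on saturday morning",
    "looking for pram recommendations for under two hundred",
    "the weather has been lovely this week for the garden",
    "we are off on holiday next month so excited to pack",
    "any good slow cooker recipes for the weekend",
    "thinking of repainting the hallway a soft green",
)

_REPLY_FILLER = (
    "thanks everyone that is really helpful",
    "following this as i was wondering the same",
    "glad it worked let us know how it goes",
    "agreed completely sensible suggestion",
)

_EMOJIS = ("\U0001F525", "\U0001F62D", "\U0001F44D", "\U0001F605",
           "\U0001F3E5", "❤️")

_PARENT_DESCRIPTIONS = (
    "proud mum of two little monkeys",
    "dad juggling work and a toddler",
    "mother of three tea drinker",
    "stay at home parent and baker",
    "father first everything else second",
)
_OTHER_DESCRIPTIONS = (
    "coffee enthusiast and runner",
    "news junkie and film fan",
    "gamer streaming most evenings",
    "cyclist baker occasional poet",
    "just here for the chat",
)

_BURN_WORDS = ("burn", "burns", "burned", "burnt")
_PURPOSE_WEIGHTS = {
    # mirrors the observed platform roles: forums seek, broadcast media offer
    "forum": (0.90, 0.02, 0.06, 0.02),
    "microblog": (0.03, 0.60, 0.10, 0.27),
    "video_comments": (0.02, 0.90, 0.03, 0.05),
}
_BURN_TYPE_WEIGHTS = (0.32, 0.24, 0.18, 0.05, 0.04, 0.03, 0.01, 0.01, 0.01,
                      0.01, 0.10)
_INJURED_WEIGHTS = (0.62, 0.33, 0.02, 0.03)


def _choice(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


class _TextFactory:
    """Deterministic slot-filled post text with gold relevance."""

    def __init__(self, taxonomy: SearchTaxonomy, rng: np.random.Generator):
        self.tax = taxonomy
        self.rng = rng
        self.fa_pool = (taxonomy.terms("fa_general")
                        + taxonomy.terms("fa_specific")
                        + taxonomy.terms("fa_food"))
        self.children_pool = taxonomy.terms("children")
        self.taxonomy_tokens = {tok for cat in taxonomy.categories.values()
                                for term in cat.terms for tok in term.split()}

    def relevant(self, purpose: str, with_child_term: bool) -> str:
        tpl = _choice(self.rng, _REL_BY_PURPOSE[purpose])
        text = tpl.format(
            burn=_choice(self.rng, self.tax.terms("burn_injury")),
            fa=_choice(self.rng, self.fa_pool),
            hot=_choice(self.rng, _HOT_THINGS),
            child=_choice(self.rng, ("boy", "girl", "one")),
        )
        if with_child_term:
            text += f" my {_choice(self.rng, self.children_pool)} was there too"
        return text

    def distractor(self) -> str:
        tpl = _choice(self.rng, _DISTRACTOR)
        return tpl.format(burnword=_choice(self.rng, _BURN_WORDS))

    def neutral(self) -> str:
        return _choice(self.rng, _NEUTRAL)

    def reply_filler(self) -> str:
        return _choice(self.rng, _REPLY_FILLER)

    def misspell(self, text: str) -> str:
        """Swap two adjacent characters in one filler word (never inside a
        taxonomy term, so gold relevance stays assertable)."""
        words = text.split()
        candidates = [i for i, w in enumerate(words)
                      if len(w) >= 5 and w.isalpha()
                      and w not in self.taxonomy_tokens]
        if not candidates:
            return text
        i = _choice(self.rng, candidates)
        w = words[i]
        j = int(self.rng.integers(1, len(w) - 2))
        words[i] = w[:j] + w[j + 1] + w[j] + w[j + 2:]
        return " ".join(words)


def _timestamp(rng: np.random.Generator, year: int) -> str:
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    hour = int(rng.integers(0, 24))
    minute = int(rng.integers(0, 60))
    return f"{year:04d}-{month:02d}-{day:02d}T{hour:02d}:{minute:02d}:00Z"


def generate_corpus(config: SynthConfig,
                    taxonomy: SearchTaxonomy | None = None
                    ) -> tuple[list[Thread], GoldLabels]:
    """Generate threads and gold labels for every configured platform.

    Each post is independently relevant with probability
    ``relevant_fraction`` (so the marginal rate is recoverable); irrelevant
    posts are distractor-sense with probability ``distractor_fraction`` and
    neutral chatter otherwise. Thread-level purpose and burn labels attach
    to the initial post. Deterministic under the config seed.
    """
    if taxonomy is None:
        taxonomy = default_taxonomy()
    total_threads = sum(p.n_threads for p in config.platforms)
    if config.relevant_fraction > 0 and total_threads == 0:
        raise ValueError("infeasible config: relevant_fraction > 0 with "
                         "zero threads")
    rng = np.random.default_rng(config.seed)
    factory = _TextFactory(taxonomy, rng)
    years, year_w = config.years_and_weights()

    threads: list[Thread] = []
    gold = GoldLabels()

    for spec in config.platforms:
        n_users = max(4, spec.n_threads)
        users = [f"{spec.platform}_user{i:05d}" for i in range(n_users)]
        for u in users:
            is_parent = rng.random() < config.parent_term_rate
            gold.user_parent[u] = is_parent
            pool = _PARENT_DESCRIPTIONS if is_parent else _OTHER_DESCRIPTIONS
            gold.user_description[u] = _choice(rng, pool)

        purpose_w = _PURPOSE_WEIGHTS[spec.kind]
        for ti in range(spec.n_threads):
            tid = f"{spec.platform}_t{ti:05d}"
            if spec.kind == "microblog":
                n_posts = 1 + int(rng.negative_binomial(spec.nb_n, spec.nb_p)) \
                    if rng.random() < 0.15 else 1
            else:
                n_posts = 1 + int(rng.negative_binomial(spec.nb_n, spec.nb_p))
            n_posts = min(n_posts, 320)
            year = int(rng.choice(years, p=year_w))
            purpose = PURPOSES[int(rng.choice(4, p=purpose_w))]
            gold.thread_purpose[tid] = purpose

            posts = []
            thread_relevant_first = False
            for pi in range(n_posts):
                pid = f"{tid}_p{pi:03d}"
                relevant = rng.random() < config.relevant_fraction
                if relevant:
                    text = factory.relevant(
                        purpose if pi == 0 else "offering_advice",
                        with_child_term=(spec.kind != "forum"))
                    if rng.random() < config.misspell_rate:
                        text = factory.misspell(text)
                elif rng.random() < config.distractor_fraction:
                    text = factory.distractor()
                elif pi > 0 and rng.random() < 0.5:
                    text = factory.reply_filler()
                else:
                    text = factory.neutral()
                if rng.random() < config.emoji_noise_rate:
                    text += " " + _choice(rng, _EMOJIS) + "!!"
                author = _choice(rng, users)
                posts.append(Post(
                    id=pid, text=text, author=author,
                    timestamp=_timestamp(rng, year),
                    user_description=gold.user_description[author]))
                gold.post_relevance[(tid, pid)] = relevant
                if pi == 0:
                    thread_relevant_first = relevant

            title = posts[0].text[:60] if spec.kind == "forum" else ""
            threads.append(Thread(id=tid, platform=spec.platform,
                                  posts=posts, title=title))
            if thread_relevant_first and purpose == "seeking_advice":
                bt = BURN_TYPES[int(rng.choice(len(BURN_TYPES),
                                               p=_BURN_TYPE_WEIGHTS))]
                inj = INJURED_PARTIES[int(rng.choice(len(INJURED_PARTIES),
                                                     p=_INJURED_WEIGHTS))]
                gold.burn_records[tid] = BurnRecord(bt, inj)
    return threads, gold


def generate_training_text(config: SynthConfig, n_sentences: int = 4000,
                           taxonomy: SearchTaxonomy | None = None
                           ) -> list[list[str]]:
    """Token sentences for embedding training, with planted co-occurrence.

    Sentences come from the same post templates as the corpus, so burn and
    first-aid terms co-occur in the injury sense while distractor senses
    co-occur with exclusion-context words, and the template vocabulary is
    guaranteed to be covered. Balanced 45/35/20 relevant/distractor/neutral
    regardless of the corpus mixing rates, which only shape evaluation data.
    """
    if n_sentences <= 0:
        raise ValueError("n_sentences must be positive")
    if taxonomy is None:
        taxonomy = default_taxonomy()
    rng = np.random.default_rng(config.seed + 101)
    factory = _TextFactory(taxonomy, rng)
    sentences = []
    for _ in range(n_sentences):
        u = rng.random()
        if u < 0.45:
            purpose = PURPOSES[int(rng.integers(4))]
            text = factory.relevant(purpose, with_child_term=rng.random() < 0.3)
        elif u < 0.80:
            text = factory.distractor()
        else:
            text = factory.neutral()
        toks = tokenize_lemmatize(text)
        if toks:
            sentences.append(toks)
    if not sentences:
        raise ValueError("generated no usable sentences")
    return sentences


def generate_topic_corpus(topic_word: np.ndarray, vocab: list[str],
                          n_docs: int, doc_len: int, alpha: float = 0.1,
                          seed: int = 0
                          ) -> tuple[list[list[str]], np.ndarray]:
    """Sample documents from a generative topic model.

    For each document draw a topic mixture from Dirichlet(alpha), then each
    token by topic then word. Returns the documents and the gold mixtures.
    """
    topic_word = np.asarray(topic_word, dtype=float)
    K, V = topic_word.shape
    if V != len(vocab):
        raise ValueError("topic_word width must match vocab size")
    if not np.allclose(topic_word.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("topic_word rows must sum to 1")
    rng = np.random.default_rng(seed)
    mixtures = rng.dirichlet(np.full(K, alpha), size=n_docs)
    docs = []
    for i in range(n_docs):
        zs = rng.choice(K, size=doc_len, p=mixtures[i])
        words = [vocab[int(rng.choice(V, p=topic_word[z]))] for z in zs]
        docs.append(words)
    return docs, mixtures


def make_disjoint_topics(K: int, words_per_topic: int = 30,
                         concentration: float = 1.3
                         ) -> tuple[np.ndarray, list[str]]:
    """K topics over disjoint vocabularies with Zipf-like within-topic decay;
    convenient ground truth for recovery tests."""
    vocab = [f"t{k}w{j:02d}" for k in range(K) for j in range(words_per_topic)]
    topic_word = np.zeros((K, K * words_per_topic))
    weights = 1.0 / np.arange(1, words_per_topic + 1) ** concentration
    weights /= weights.sum()
    for k in range(K):
        topic_word[k, k * words_per_topic:(k + 1) * words_per_topic] = weights
    return topic_word, vocab
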