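# Methods

This note documents the models and procedures implemented in `convomine`,
the parameters that matter, the synthetic data they are exercised on, and
the design decisions taken where the design was genuinely open.

## Search taxonomy and query composition

The packaged taxonomy (`src/convomine/data/taxonomy.json`) has six
categories: 9 burn-injury terms, 10 general first-aid terms, 25 specific
remedy terms, 11 food-remedy terms, 16 child-reference terms and 9
exclusion terms flagging non-injury senses. The specific-remedy list in the
source material repeats "lotion"; categories are duplicate-free sets, so it
is stored once.

Three queries are composed per platform — the burn group crossed with one
first-aid group each — because search backends cap query size; the
microblog profile additionally attaches the child group (the platform is
not parent-specific) and the exclusion terms, under a 1024-character render
budget. A query that cannot fit is an error naming the query, never a
silent truncation. Matching is case-insensitive on raw text at word
boundaries; multiword terms match as contiguous phrases; the ambiguous
child term "yo" matches standalone or adjacent to a number ("3 yo", "3yo")
but never inside an alphabetic word. Whole threads are retained when any
post (or the title) matches any query, and results are merged
duplicate-free. Matching is monotone: adding a term to a required group can
only grow the matched set; adding an exclusion can only shrink it.

## Normalization

`strip_symbols` keeps letters, digits and whitespace and removes everything
else — covering the emoji blocks (Emoticons; Miscellaneous Symbols and
Pictographs; Transport and Map Symbols; Supplemental Symbols and
Pictographs), variation selectors/ZWJ and all punctuation in one
deterministic, idempotent pass. Combining marks are dropped too, which is
acceptable for informal English text.

The lemmatizer is a frozen rule-based English lemmatizer: an
irregular-form table (burnt→burn, children→child, frozen→freeze, …) plus
plural and -ed/-ing suffix rules guarded by the classic consonant–vowel
measure, with undoubling ("stopped"→"stop") and silent-e restoration on
short CVC stems ("making"→"make"). Lemmas are computed to a fixpoint, so
the whole pipeline is idempotent by construction. It is deliberately
conservative and occasionally over-strips rare forms ("morning"→"morn");
for relevance scoring and topic modeling this is harmless because the same
lemmatizer is applied to the training text, the lexicons and the units.
No installed lemmatizer or stopword resource is relied on: the stopword
list (`data/stopwords.txt`, ~170 function words including
apostrophe-stripped contraction forms) is frozen in the repository so that
results are reproducible byte for byte. Numerals are retained ("20
minutes" is topically meaningful).

## Embeddings

`train_embeddings` is skip-gram with negative sampling implemented in
numpy. Training pairs (fixed window, default 5) are shuffled with a seeded
generator and processed in mini-batches (default 256) with a linearly
decaying learning rate (initial 0.05), 5 negatives drawn from the
unigram^0.75 distribution. Everything derives from a single seeded
generator and updates are applied with deterministic scatter-adds, so a
fixed seed reproduces the vectors exactly on one CPU. Defaults: d = 50,
5 epochs, min_count = 2. Mini-batching accumulates within-batch gradients
rather than applying them sequentially; on corpora whose vocabulary is not
absurdly small relative to the batch this is indistinguishable in practice,
and the batch size is a parameter.

Subword handling is post hoc: after training, each character 3–5-gram of
the padded word (`<word>`) receives the mean vector of the vocabulary words
containing it, and an out-of-vocabulary token is embedded as the mean of
its known n-gram vectors. This gives typo robustness ("bilster" lands near
"blister") without training n-gram parameters jointly.

## Dual-lexicon relevance filter

Seeds are lemma-level tokens of the taxonomy terms: positive = burn +
general/specific/food first-aid terms; negative = the exclusion terms by
default. The published construction of the negative list is ambiguous, so
an alternative — nearest neighbours of the sign-flipped positive seed
vectors — is available behind `negative_strategy="negated_vectors"`;
neither is claimed to be the original authors'. Expansion adds the k = 50
vocabulary terms with the highest maximum cosine to any seed (a centroid
mode exists), ties broken lexicographically, seeds excluded.

A unit's score against a lexicon is the mean cosine over all token × term
pairs — not a per-token maximum — computed on row-normalized matrices and
therefore invariant to positive rescaling of the embedding space; a naive
double-loop oracle agrees to 1e-9. Tokens without vectors are skipped and
excluded from the token count; a unit with nothing scorable is undefined
and classified irrelevant by the pipeline (conservative). Classification is
relevant iff pos_mean ≥ θ⁺ and neg_mean ≤ θ⁻, both inclusive.

Thresholds are per-platform artifacts. Calibration grid-searches the
observed score values (quantile-thinned to 128 candidates per axis),
maximizing F1 on the relevant class against labelled examples, with a
deterministic tie-break (smallest θ⁺, then largest θ⁻). On real data the
labels would come from manual coding of a sample; on synthetic data the
generator's gold labels play that role.

## Topic modeling

LDA via batch variational inference (scikit-learn backend) with symmetric
priors α = 1/K and β = 0.01, K fixed at 11 — K is a configuration value,
not a derived quantity. Documents are whole threads on forums and
individual tweets/comments elsewhere. Multi-topic membership assigns every
topic with posterior weight ≥ τ (default 0.25, surfaced in every report),
falling back to the argmax topic (all of them under ties) when none
reaches τ. Top-word lists break probability ties lexicographically.
Overlap between two topics is reported as a count and a percentage of all
documents (1 dp); the multi-topic rate at 2 dp. Topic interpretation is a
human step; the pipeline only emits top-word sheets and overlap matrices to
support it.

## Characterization

All tables flow through one rounding convention: `pct(num, den, d)` is
100·num/den rounded half-up (decimal arithmetic, not banker's rounding) at
the table's decimal places — 1 dp for purpose/prevalence tables, 0 dp for
crosstab row percentages, 2 dp for yearly tables. Filter reductions are
reported at 0 dp. Margins are computed as sums, so conservation is
structural. Purpose, burn-type and injured-party labels are inputs (gold or
manually coded), never model output. Distinct users per thread count unique
author ids, with anonymous posts counted as singleton authors. Unparseable
timestamps are excluded from yearly tables but counted and reported.
Parent-voice counts scan one description per distinct user with
word-boundary phrase matching over a configurable parent/child term list.

## Synthetic data

The generator plants exactly the structure the pipeline assumes, by
construction rather than by learning:

- Posts are slot-filled templates. Relevant posts always contain at least
  one burn term and one first-aid term (plus a child term on non-forum
  platforms), so label consistency is assertable with the query matcher.
  Irrelevant posts are distractor-sense templates (burn calories, burnout,
  burn bridges, heartburn) at the configured fraction of irrelevant posts
  (default 40%), otherwise neutral chatter.
- Each post is independently relevant with the configured probability
  (default 30%), so the marginal rate is recoverable within binomial error;
  thread-level purpose/burn labels attach to the initial post.
- Thread lengths are shifted negative binomials: heavy-tailed forum threads
  (mean ≈ 16, clipped at 320 posts), mostly single-post microblog threads,
  video comment sections of a dozen comments — chosen to resemble observed
  parenting-forum ranges (single posts up to a few hundred).
- Timestamps span 2004–2020 with linearly increasing yearly intensity by
  default (social-media volume grows); user descriptions carry a
  parent/child term at rate 0.06; emoji noise at 0.2 and adjacent-character
  misspellings at 0.1 exercise symbol stripping and subword inference
  (misspellings never hit taxonomy terms, preserving gold labels).
- Embedding training text is generated from the same templates (45%
  relevant-sense, 35% distractor, 20% neutral), which guarantees the
  template vocabulary is covered and the two senses of "burn" have
  separable contexts.
- `generate_topic_corpus` samples documents from an explicit topic-word
  matrix with Dirichlet(α) mixtures; `make_disjoint_topics` provides
  disjoint-vocabulary ground truth with Zipf-like within-topic decay.

What passing on this data shows — and does not. Template text makes sense
separation much crisper than real social-media language: the filter reaches
F1 ≈ 1.0 here, which validates the machinery (scoring, calibration,
monotonicity, determinism), not a field-performance claim. Real posts have
richer vocabulary, spelling variation beyond single transpositions,
code-switching, sarcasm and topic drift; expect materially lower F1 and
platform-dependent thresholds there.

## Problem sizes and numerical choices

The shipped evaluation sizes — 2,000 posts with 4,000 training sentences
and d = 50 for the filter study; 600 documents × 60 tokens for K = 3 topic
recovery; 200 randomized fixtures for conservation properties — are large
enough that the measured rates are stable across seeds while keeping any
single run in the tens of seconds. Distribution-row normalization is
checked at 1e-6; the scoring oracle at 1e-9; cosine of a zero vector is
defined as 0. Hungarian matching (`scipy.optimize.linear_sum_assignment`)
makes topic-recovery scoring invariant to label permutation.

## Known limitations

- The lemmatizer and stopword list are English-only and heuristic.
- Subword vectors are induced post hoc, not trained; severely garbled
  tokens may receive weak vectors.
- The calibration objective assumes labelled examples exist for every
  platform; with a single-class sample it refuses rather than guesses.
- K and τ are configuration values; no coherence-based model selection is
  attempted.
- The generator does not imitate real users or platforms; it is an
  instrument for testing the pipeline, not a simulator of discourse.
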