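"""Lexicon expansion, pairwise-mean scoring (against a naive oracle),
dual-threshold classification and calibration, and corpus filtering."""

import numpy as np
import pytest

from convomine.embedding import EmbeddingModel, cosine
from convomine.io import Post, Thread
from convomine.lexicon import FORUM_PROFILE
from convomine.relevance import (ExpandedLexicon, FilterReport,
                                 RelevanceScore, ThresholdPair,
                                 calibrate_thresholds, classify,
                                 expand_lexicon, filter_corpus, score_unit)
from conftest import make_model


def naive_score(tokens, lex, model):
    """Independent double-loop pairwise-mean similarity."""
    sims = []
    for t in tokens:
        vt = model.vector(t)
        if vt is None:
            continue
        for term in lex.combined:
            vterm = model.vector(term)
            if vterm is not None:
                sims.append(cosine(vt, vterm))
    return float(np.mean(sims)) if sims else None


class TestExpandLexicon:
    def test_k_zero_returns_seeds_only(self, toy_model):
        lex = expand_lexicon(toy_model, ("burn",), 0, "relevant")
        assert lex.combined == ("burn",)

    def test_k_fifty_bounds_combined_size(self, planted_model):
        lex = expand_lexicon(planted_model, ("burn", "scald"), 50, "relevant")
        assert len(lex.combined) <= 2 + 50
        assert not set(lex.seed_terms) & set(lex.neighbor_terms)

    def test_planted_nearest_neighbor_recovered(self, toy_model):
        lex = expand_lexicon(toy_model, ("burn",), 1, "relevant")
        assert lex.neighbor_terms == ("scald",)

    def test_no_seed_vector_raises(self, toy_model):
        with pytest.raises(ValueError):
            expand_lexicon(toy_model, ("zzz",), 5, "relevant")

    def test_negated_mode_finds_antipodal_terms(self):
        model = make_model({"a": [1.0, 0.0], "b": [-1.0, 0.1],
                            "c": [0.9, 0.1]})
        lex = expand_lexicon(model, ("a",), 1, "irrelevant", negate=True)
        assert lex.neighbor_terms == ("b",)


class TestScoreUnit:
    def test_self_similarity_is_one(self, toy_model):
        pos = ExpandedLexicon("relevant", ("burn",), ())
        neg = ExpandedLexicon("irrelevant", ("calorie",), ())
        s = score_unit(["burn"], pos, neg, toy_model)
        assert s.pos_mean == pytest.approx(1.0)
        assert s.n_tokens == 1 and s.defined

    def test_empty_tokens_undefined(self, toy_model):
        pos = ExpandedLexicon("relevant", ("burn",), ())
        neg = ExpandedLexicon("irrelevant", ("calorie",), ())
        s = score_unit([], pos, neg, toy_model)
        assert not s.defined and s.n_tokens == 0

    def test_hand_computed_mean_of_four_cosines(self):
        # two orthogonal tokens, two positive terms with known geometry:
        # cos(t1,p1)=1, cos(t1,p2)=0, cos(t2,p1)=0, cos(t2,p2)=0 -> mean 0.25
        model = make_model({"t1": [1, 0, 0], "t2": [0, 1, 0],
                            "p1": [1, 0, 0], "p2": [0, 0, 1]})
        pos = ExpandedLexicon("relevant", ("p1", "p2"), ())
        neg = ExpandedLexicon("irrelevant", ("p2",), ())
        s = score_unit(["t1", "t2"], pos, neg, model)
        assert s.pos_mean == pytest.approx(0.25, abs=1e-12)

    def test_vectorized_agrees_with_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        vocab = [f"w{i}" for i in range(40)]
        model = EmbeddingModel(dim=10, vocab=vocab,
                               vectors=rng.normal(size=(40, 10)),
                               subword=False)
        pos = ExpandedLexicon("relevant", tuple(vocab[:4]), tuple(vocab[4:9]))
        neg = ExpandedLexicon("irrelevant", tuple(vocab[9:12]), ())
        for _ in range(100):
            tokens = list(rng.choice(vocab, size=rng.integers(1, 15)))
            s = score_unit(tokens, pos, neg, model)
            assert abs(s.pos_mean - naive_score(tokens, pos, model)) < 1e-9
            assert abs(s.neg_mean - naive_score(tokens, neg, model)) < 1e-9

    def test_scores_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(6)
        vocab = [f"w{i}" for i in range(20)]
        vecs = rng.normal(size=(20, 6))
        m1 = EmbeddingModel(dim=6, vocab=vocab, vectors=vecs, subword=False)
        m2 = EmbeddingModel(dim=6, vocab=vocab, vectors=vecs * 37.5,
                            subword=False)
        pos = ExpandedLexicon("relevant", tuple(vocab[:3]), ())
        neg = ExpandedLexicon("irrelevant", tuple(vocab[3:6]), ())
        tokens = vocab[6:12]
        s1, s2 = (score_unit(tokens, pos, neg, m) for m in (m1, m2))
        assert s1.pos_mean == pytest.approx(s2.pos_mean, abs=1e-12)
        assert s1.neg_mean == pytest.approx(s2.neg_mean, abs=1e-12)


class TestClassify:
    thr = ThresholdPair("p", 0.5, 0.0)

    def test_clearly_relevant(self):
        assert classify(RelevanceScore(1.0, -1.0, 3), self.thr) == "relevant"

    def test_boundary_is_inclusive(self):
        assert classify(RelevanceScore(0.5, 0.0, 3), self.thr) == "relevant"

    def test_high_negative_similarity_rejected(self):
        assert classify(RelevanceScore(0.2, 0.9, 3), self.thr) == "irrelevant"

    def test_undefined_score_raises(self):
        with pytest.raises(ValueError):
            classify(RelevanceScore(0.0, 0.0, 0), self.thr)


def _scores(pos, neg, labels):
    return [(RelevanceScore(p, n, 1), y) for p, n, y in zip(pos, neg, labels)]


class TestCalibrate:
    def test_perfect_separation_reaches_f1_one(self):
        scored = _scores([0.9, 0.8, 0.1, 0.2], [-0.5, -0.4, 0.6, 0.7],
                         [True, True, False, False])
        thr = calibrate_thresholds(scored)
        assert thr.provenance["objective_value"] == pytest.approx(1.0)
        preds = [classify(s, thr) == "relevant" for s, _ in scored]
        assert preds == [True, True, False, False]

    def test_single_class_sample_rejected(self):
        with pytest.raises(ValueError):
            calibrate_thresholds(_scores([0.9, 0.1], [0, 0], [True, True]))

    def test_tie_break_smallest_theta_pos_largest_theta_neg(self):
        # F1=1 at (0.2, 0.1), (0.6, 0.1) and (0.6, 0.5): the tie resolves
        # to the smallest theta_pos first, then the largest theta_neg
        scored = _scores([0.6, 0.2], [0.1, 0.5], [True, False])
        thr = calibrate_thresholds(scored)
        assert thr.provenance["objective_value"] == pytest.approx(1.0)
        assert thr.theta_pos == pytest.approx(0.2)
        assert thr.theta_neg == pytest.approx(0.1)

    def test_uninformative_scores_stay_near_base_rate(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(size=50)
        neg = rng.uniform(size=50)
        labels = list(rng.random(50) < 0.4)
        scored = _scores(pos, neg, labels)
        thr = calibrate_thresholds(scored)
        # exhaustive oracle over the same candidate grid
        best = 0.0
        for tp_ in np.unique(pos):
            for tn_ in np.unique(neg):
                pred = (pos >= tp_) & (neg <= tn_)
                y = np.array(labels)
                tp = (pred & y).sum()
                denom = 2 * tp + (pred & ~y).sum() + (~pred & y).sum()
                best = max(best, 2 * tp / denom if denom else 0.0)
        assert thr.provenance["objective_value"] == pytest.approx(best)

    def test_tightening_thresholds_never_grows_retained_set(self):
        rng = np.random.default_rng(1)
        scores = [RelevanceScore(p, n, 1) for p, n in
                  rng.uniform(-1, 1, size=(200, 2))]

        def retained(tp_, tn_):
            thr = ThresholdPair("p", tp_, tn_)
            return {i for i, s in enumerate(scores)
                    if classify(s, thr) == "relevant"}

        base = retained(0.0, 0.0)
        assert retained(0.3, 0.0) <= base   # raising theta_pos
        assert retained(0.0, -0.3) <= base  # lowering theta_neg


class TestFilterCorpus:
    def test_report_reduction_percentages(self):
        assert FilterReport("mumsnet", "title_plus_main_post",
                            1972, 594).reduction_pct == 70
        assert FilterReport("p", "per_tweet", 10, 10).reduction_pct == 0.0

    def test_forum_filtering_keeps_whole_threads(self, toy_model):
        pos = ExpandedLexicon("relevant", ("burn", "scald", "water"), ())
        neg = ExpandedLexicon("irrelevant", ("calorie", "gym"), ())
        thr = ThresholdPair("forum", 0.5, 0.3)
        relevant = Thread("r", "forum", [
            Post("p0", "burn scald water"), Post("p1", "calorie gym")])
        irrelevant = Thread("i", "forum", [Post("p0", "calorie gym calorie")])
        retained, report = filter_corpus(
            [relevant, irrelevant], FORUM_PROFILE, pos, neg, toy_model, thr)
        assert [t.id for t in retained] == ["r"]
        assert retained[0].n_posts == 2  # replies kept with the thread
        assert (report.n_before, report.n_after) == (2, 1)
        assert report.reduction_pct == 50
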