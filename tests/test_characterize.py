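"""Percent convention, thread statistics and the report tabulators, each
checked against brute-force recomputation."""

from collections import Counter

import numpy as np
import pytest

from convomine.characterize import (BURN_TYPES, INJURED_PARTIES, BurnRecord,
                                    burn_crosstab, parent_voice, pct,
                                    purpose_table, term_prevalence,
                                    thread_stats, top_frequent_words,
                                    yearly_counts, PURPOSES)
from convomine.io import Post, Thread


class TestPct:
    @pytest.mark.parametrize("num, den, dp, expected", [
        (112, 116, 1, 96.6),
        (0, 94, 1, 0.0),
        (12, 1905, 2, 0.63),
        (138, 2275, 0, 6.0),
        (30, 94, 0, 32.0),
        (27, 275, 1, 9.8),
        (5, 1000, 0, 1.0),   # exact half rounds up, not to even
        (25, 1000, 1, 2.5),
    ])
    def test_half_up_rounding(self, num, den, dp, expected):
        assert pct(num, den, dp) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            pct(1, 0)


def _thread(tid, n_posts, authors=None):
    authors = authors or [f"u{i}" for i in range(n_posts)]
    return Thread(id=tid, platform="forum",
                  posts=[Post(f"{tid}p{i}", "text", author=a)
                         for i, a in enumerate(authors)])


class TestThreadStats:
    def test_single_thread(self):
        st = thread_stats([_thread("a", 5)])
        assert st.posts.mean == 5 and (st.posts.min, st.posts.max) == (5, 5)
        assert st.posts.sd == 0.0

    def test_two_threads_mean(self):
        st = thread_stats([_thread("a", 2), _thread("b", 4)])
        assert st.posts.mean == 3.0

    def test_anonymous_posts_count_as_distinct_users(self):
        t = _thread("a", 3, authors=["u1", "", ""])
        assert thread_stats([t]).users.max == 3

    def test_matches_brute_force_on_random_threads(self):
        rng = np.random.default_rng(2)
        threads = [_thread(f"t{i}", int(rng.integers(1, 40)))
                   for i in range(50)]
        st = thread_stats(threads)
        sizes = np.array([t.n_posts for t in threads], dtype=float)
        assert st.posts.mean == pytest.approx(sizes.mean())
        assert st.posts.sd == pytest.approx(sizes.std(ddof=1))
        assert (st.posts.min, st.posts.max) == (sizes.min(), sizes.max())


class TestPurposeTable:
    def test_printed_seeking_row(self):
        labels = ["seeking_advice"] * 112 + ["experience_sharing"] * 4
        tab = purpose_table(labels).set_index("purpose")
        assert tab.loc["seeking_advice", "count"] == 112
        assert tab.loc["seeking_advice", "pct"] == 96.6

    def test_all_offering(self):
        tab = purpose_table(["offering_advice"] * 7).set_index("purpose")
        assert tab.loc["offering_advice", "pct"] == 100.0
        assert tab.drop("offering_advice")["count"].sum() == 0

    def test_counts_conserved_and_match_brute_force(self):
        rng = np.random.default_rng(3)
        labels = [PURPOSES[i] for i in rng.integers(0, 4, size=200)]
        tab = purpose_table(labels)
        assert tab["count"].sum() == 200
        brute = Counter(labels)
        for _, row in tab.iterrows():
            assert row["count"] == brute.get(row["purpose"], 0)
            assert row["pct"] == pct(row["count"], 200, 1)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            purpose_table(["selling_advice"])


class TestBurnCrosstab:
    def test_printed_contact_row_percentage(self):
        records = ([BurnRecord("contact", "adult")] * 30
                   + [BurnRecord("sunburn", "adult")] * 64)
        tab = burn_crosstab(records)
        assert tab.loc["contact", "total"] == 30
        assert tab.loc["contact", "total_pct"] == 32.0

    def test_empty_input_all_zero(self):
        tab = burn_crosstab([])
        assert tab["total"].sum() == 0

    def test_margins_equal_sums_on_random_fixtures(self):
        rng = np.random.default_rng(4)
        records = [BurnRecord(BURN_TYPES[i], INJURED_PARTIES[j])
                   for i, j in zip(rng.integers(0, 11, 300),
                                   rng.integers(0, 4, 300))]
        tab = burn_crosstab(records)
        body = tab.drop("total").drop(columns=["total", "total_pct"])
        assert (body.sum(axis=1) == tab.drop("total")["total"]).all()
        assert (body.sum(axis=0) == tab.loc["total",
                                            list(INJURED_PARTIES)]).all()
        assert tab.loc["total", "total"] == 300


class TestYearlyCounts:
    def test_single_year_is_hundred_percent(self):
        tab, bad = yearly_counts(["2019-05-01T00:00:00Z"] * 4)
        assert bad == 0
        assert tab.loc[0, "pct"] == 100.0

    def test_even_split(self):
        tab, _ = yearly_counts(["2019-01-01", "2019-06-01",
                                "2020-01-01", "2020-06-01"])
        assert list(tab["pct"]) == [50.0, 50.0]

    def test_unparseable_excluded_but_counted(self):
        tab, bad = yearly_counts(["2019-01-01", "not a date", ""])
        assert bad == 2
        assert tab["count"].sum() == 1

    def test_matches_brute_force_histogram(self):
        rng = np.random.default_rng(5)
        years = rng.integers(2004, 2021, size=120)
        ts = [f"{y}-03-0{1 + i % 9}T12:00:00Z" for i, y in enumerate(years)]
        tab, _ = yearly_counts(ts)
        brute = Counter(int(y) for y in years)
        assert tab["count"].sum() == 120
        for _, row in tab.iterrows():
            assert row["count"] == brute.get(row["year"], 0)
            assert row["pct"] == pct(row["count"], 120, 2)


class TestTermPrevalence:
    def test_absent_and_universal_terms(self):
        units = ["cool water helps", "more water please", "water again"]
        tab = term_prevalence(units, ["butter", "water"]).set_index("term")
        assert tab.loc["butter", "pct"] == 0.0
        assert tab.loc["water", "pct"] == 100.0

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(6)
        words = ["water", "butter", "gel", "ice", "plain"]
        units = [" ".join(rng.choice(words, size=3)) for _ in range(80)]
        tab = term_prevalence(units, words[:4]).set_index("term")
        for term in words[:4]:
            brute = sum(1 for u in units if term in u.split())
            assert tab.loc[term, "count"] == brute


class TestTopFrequentWords:
    def test_most_repeated_word_first(self):
        corpus = [["water", "water", "gel"], ["water"]]
        assert top_frequent_words(corpus)[0] == ("water", 3)

    def test_pronoun_only_corpus_is_empty(self):
        assert top_frequent_words([["he", "she", "it"], ["they"]]) == []

    def test_matches_brute_force_counter(self):
        rng = np.random.default_rng(7)
        vocab = [f"w{i}" for i in range(20)]
        corpus = [list(rng.choice(vocab, size=10)) for _ in range(40)]
        got = top_frequent_words(corpus, n=50)
        brute = Counter(t for d in corpus for t in d)
        assert dict(got) == dict(brute)
        counts = [c for _, c in got]
        assert counts == sorted(counts, reverse=True)


class TestParentVoice:
    def test_planted_fixture(self):
        descs = ["proud mum of two"] * 3 + ["coffee lover"] * 7
        assert parent_voice(descs, decimals=0) == (3, 30.0)

    def test_no_parent_terms(self):
        assert parent_voice(["coffee lover", "gamer"]) == (0, 0.0)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        pool = ["dad of one", "likes tea", "mother hen", "night owl"]
        descs = [pool[i] for i in rng.integers(0, 4, size=60)]
        count, p = parent_voice(descs, parent_terms=("dad", "mother"))
        brute = sum(1 for d in descs if "dad" in d or "mother" in d)
        assert count == brute and p == pct(brute, 60, 0)
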