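"""Descriptive characterization of relevant conversations.

Reproduces the shapes of the study-style report tables: thread/user
statistics, purpose-of-post tabulation, burn-type x injured-party crosstab
with margins, per-calendar-year volumes, term prevalence across units,
top-50 frequent words, and parent-voice counts from user descriptions.

All percentages go through :func:`pct` — exact half-up rounding at the
table's decimal places — so every printed percentage is reproducible from
its count cells.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io import Thread
from .lexicon import term_in_text
from .preprocess import DEFAULT_STOPWORDS, load_pronouns

PURPOSES = ("seeking_advice", "offering_advice", "experience_sharing", "news")

BURN_TYPES = ("contact", "sunburn", "scald", "chemical", "steam", "friction",
              "cold", "firework", "flame", "laser", "unspecified")
INJURED_PARTIES = ("adult", "child", "pet", "unspecified")

DEFAULT_PARENT_TERMS = (
    "mum", "mummy", "mom", "mommy", "dad", "daddy", "mother", "father",
    "parent", "parents", "grandma", "grandad", "nan", "carer", "my kid",
    "little one", "toddler", "baby", "son", "daughter",
)


def pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100*numerator/denominator rounded half-up to ``decimals`` places.

    The single rounding convention behind every percentage cell, so each
    cell can be recomputed exactly from its counts.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator))
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


# --- thread statistics --------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    min: int
    max: int


@dataclass(frozen=True)
class ThreadStats:
    n_threads: int
    posts: SummaryStats
    users: SummaryStats


def _summary(values: list[int]) -> SummaryStats:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return SummaryStats(mean=float(arr.mean()), sd=sd,
                        min=int(arr.min()), max=int(arr.max()))


def thread_stats(threads: list[Thread]) -> ThreadStats:
    """Mean, sample SD and range of posts and distinct users per thread."""
    if not threads:
        raise ValueError("no threads")
    return ThreadStats(
        n_threads=len(threads),
        posts=_summary([t.n_posts for t in threads]),
        users=_summary([t.n_users for t in threads]))


# --- tabulations --------------------------------------------------------------

def purpose_table(labels: list[str], decimals: int = 1) -> pd.DataFrame:
    """Counts and percentages of initial-post purpose, one row per category."""
    unknown = set(labels) - set(PURPOSES)
    if unknown:
        raise ValueError(f"unknown purpose labels: {sorted(unknown)}")
    n = len(labels)
    counts = Counter(labels)
    rows = [{"purpose": p, "count": counts.get(p, 0),
             "pct": pct(counts.get(p, 0), n, decimals) if n else 0.0}
            for p in PURPOSES]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BurnRecord:
    burn_type: str
    injured: str

    def __post_init__(self):
        if self.burn_type not in BURN_TYPES:
            raise ValueError(f"unknown burn type {self.burn_type!r}")
        if self.injured not in INJURED_PARTIES:
            raise ValueError(f"unknown injured party {self.injured!r}")


def burn_crosstab(records: list[BurnRecord],
                  decimals: int = 0) -> pd.DataFrame:
    """Burn-type x injured-party crosstab with margins and a row-total
    percentage-of-grand-total column."""
    table = pd.DataFrame(0, index=list(BURN_TYPES),
                         columns=list(INJURED_PARTIES), dtype=int)
    for r in records:
        table.loc[r.burn_type, r.injured] += 1
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    grand = int(table.loc["total", "total"])
    table["total_pct"] = [
        pct(int(c), grand, decimals) if grand else 0.0
        for c in table["total"]]
    return table


def yearly_counts(timestamps: list[str],
                  decimals: int = 2) -> tuple[pd.DataFrame, int]:
    """Per-calendar-year counts and percentages.

    Returns (table, n_unparseable); unparseable timestamps are excluded
    from the table but reported. The table covers every year in the
    observed range, including zero-count years.
    """
    parsed = pd.to_datetime(pd.Series(timestamps, dtype="object"),
                            errors="coerce", format="mixed", utc=True) \
        if timestamps else pd.Series([], dtype="datetime64[ns, UTC]")
    n_bad = int(parsed.isna().sum())
    years = parsed.dropna().dt.year.astype(int)
    if years.empty:
        return pd.DataFrame(columns=["year", "count", "pct"]), n_bad
    total = len(years)
    counts = years.value_counts()
    rows = [{"year": y, "count": int(counts.get(y, 0)),
             "pct": pct(int(counts.get(y, 0)), total, decimals)}
            for y in range(years.min(), years.max() + 1)]
    return pd.DataFrame(rows), n_bad


def term_prevalence(units: list[str], terms,
                    decimals: int = 1) -> pd.DataFrame:
    """Percentage of units containing each term (word-boundary phrase
    matching, as used by query matching)."""
    n = len(units)
    rows = []
    for term in terms:
        count = sum(1 for u in units if term_in_text(term, u))
        rows.append({"term": term, "count": count,
                     "pct": pct(count, n, decimals) if n else 0.0})
    return pd.DataFrame(rows)


def top_frequent_words(corpus, n: int = 50,
                       exclusions: frozenset[str] | None = None
                       ) -> list[tuple[str, int]]:
    """The n most frequent tokens, excluding stopwords and pronouns;
    descending count with lexicographic tie-break."""
    if exclusions is None:
        exclusions = DEFAULT_STOPWORDS | load_pronouns()
    counts = Counter(t for doc in corpus for t in doc if t not in exclusions)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:n]


def parent_voice(descriptions: list[str], parent_terms=None,
                 decimals: int = 0) -> tuple[int, float]:
    """Count and percentage of user descriptions containing a parent or
    child descriptor term."""
    if parent_terms is None:
        parent_terms = DEFAULT_PARENT_TERMS
    count = sum(1 for d in descriptions
                if any(term_in_text(t, d) for t in parent_terms))
    n = len(descriptions)
    return count, (pct(count, n, decimals) if n else 0.0)


# --- combined report ----------------------------------------------------------

def build_report(threads: list[Thread], purposes: dict[str, str],
                 burn_records: list[BurnRecord],
                 token_corpus, prevalence_terms,
                 descriptions: list[str] | None = None) -> dict:
    """Assemble the full characterization for one platform's retained
    corpus. Gold or manually coded labels are inputs, not model output."""
    stats = thread_stats(threads) if threads else None
    labels = [purposes[t.id] for t in threads if t.id in purposes]
    timestamps = [p.timestamp for t in threads for p in t.posts if p.timestamp]
    units = [t.main_unit_text() for t in threads]
    report = {
        "thread_stats": stats,
        "purpose_table": purpose_table(labels),
        "burn_crosstab": burn_crosstab(burn_records),
        "yearly": yearly_counts(timestamps),
        "term_prevalence": term_prevalence(units, prevalence_terms),
        "top_words": top_frequent_words(token_corpus),
    }
    if descriptions is not None:
        report["parent_voice"] = parent_voice(descriptions)
    return report
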