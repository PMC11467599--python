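"""Search-term taxonomy, boolean query composition and term matching.

The taxonomy groups search terms into six categories: burn-injury terms,
three flavours of first-aid terms (general, specific remedies, food-based
folk remedies), references to children, and exclusion terms that flag
common non-injury senses ("burn calories", "burnout", "burn bridges").

Queries pair the burn-injury group with one first-aid group each —
three queries per platform — with child-reference and exclusion groups
attached only on platforms that are not parent-specific. Matching is
case-insensitive on raw text at word boundaries; multiword terms match
as contiguous phrases.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .io import Thread

CATEGORY_NAMES = ("burn_injury", "fa_general", "fa_specific", "fa_food",
                  "children", "exclusion")

ANALYSIS_UNITS = ("title_plus_main_post", "per_tweet", "per_comment")


class BudgetExceededError(ValueError):
    """A rendered query does not fit the platform's character budget."""


@dataclass(frozen=True)
class TermCategory:
    name: str
    terms: tuple[str, ...]

    def __post_init__(self):
        if not self.terms:
            raise ValueError(f"category {self.name!r} has no terms")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError(f"category {self.name!r} has duplicate terms")
        if any(t != t.lower() for t in self.terms):
            raise ValueError(f"category {self.name!r} has non-lowercase terms")


@dataclass(frozen=True)
class SearchTaxonomy:
    categories: dict[str, TermCategory]

    def __post_init__(self):
        missing = set(CATEGORY_NAMES) - set(self.categories)
        if missing:
            raise ValueError(f"missing categories: {sorted(missing)}")

    def __getitem__(self, name: str) -> TermCategory:
        return self.categories[name]

    def terms(self, name: str) -> tuple[str, ...]:
        return self.categories[name].terms


def default_taxonomy() -> SearchTaxonomy:
    """The packaged taxonomy of burn first aid search terms.

    The specific-remedy list in the source material repeats "lotion";
    it is stored once here, leaving 25 unique specific terms.
    """
    raw = json.loads(
        resources.files("convomine.data").joinpath("taxonomy.json").read_text()
    )
    return SearchTaxonomy(
        categories={name: TermCategory(name, tuple(raw[name]))
                    for name in CATEGORY_NAMES}
    )


@dataclass(frozen=True)
class PlatformProfile:
    """Per-platform search and analysis configuration.

    Parent-specific platforms (parenting forums) skip the child-reference
    group and exclusion terms; general platforms need both. ``analysis_unit``
    names the text span scored for relevance downstream.
    """

    platform: str
    analysis_unit: str
    include_children: bool = False
    include_exclusions: bool = False
    char_budget: int | None = None  # None = unlimited

    def __post_init__(self):
        if self.analysis_unit not in ANALYSIS_UNITS:
            raise ValueError(f"unknown analysis unit {self.analysis_unit!r}")
        if self.char_budget is not None and self.char_budget <= 0:
            raise ValueError("char_budget must be positive")


FORUM_PROFILE = PlatformProfile("forum", "title_plus_main_post")
MICROBLOG_PROFILE = PlatformProfile(
    "microblog", "per_tweet", include_children=True,
    include_exclusions=True, char_budget=1024)
VIDEO_COMMENTS_PROFILE = PlatformProfile("video_comments", "per_comment")

DEFAULT_PROFILES = {
    "mumsnet": FORUM_PROFILE,
    "netmums": FORUM_PROFILE,
    "reddit": FORUM_PROFILE,
    "twitter": MICROBLOG_PROFILE,
    "youtube": VIDEO_COMMENTS_PROFILE,
    "forum": FORUM_PROFILE,
    "microblog": MICROBLOG_PROFILE,
    "video_comments": VIDEO_COMMENTS_PROFILE,
}


@dataclass(frozen=True)
class Query:
    """Conjunction over OR-groups of terms, minus excluded terms."""

    platform: str
    required_groups: tuple[tuple[str, ...], ...]
    excluded_terms: tuple[str, ...] = ()
    char_budget: int | None = None
    name: str = ""

    def __post_init__(self):
        if not self.required_groups or any(not g for g in self.required_groups):
            raise ValueError("required_groups must be nonempty")


# --- term matching ---------------------------------------------------------

# "yo" is matched standalone or immediately after a number ("3 yo", "3yo")
# but never inside an alphabetic word; other terms use plain \w boundaries.
_NUMERIC_ADJACENT_TERMS = frozenset({"yo", "mo"})


@lru_cache(maxsize=4096)
def _term_pattern(term: str) -> re.Pattern:
    parts = [re.escape(tok) for tok in term.split()]
    body = r"\s+".join(parts)
    if term in _NUMERIC_ADJACENT_TERMS:
        return re.compile(rf"(?<![a-z]){body}(?![a-z0-9])", re.IGNORECASE)
    return re.compile(rf"(?<!\w){body}(?!\w)", re.IGNORECASE)


def term_in_text(term: str, text: str) -> bool:
    """Case-insensitive word-boundary containment; phrases are contiguous."""
    return bool(_term_pattern(term).search(text))


def match_text(text: str, query: Query) -> bool:
    """True iff every required group has a hit and no excluded term occurs."""
    if not text:
        return False
    for group in query.required_groups:
        if not any(term_in_text(t, text) for t in group):
            return False
    return not any(term_in_text(t, text) for t in query.excluded_terms)


# --- query composition and rendering ---------------------------------------

_FA_GROUPS = ("fa_general", "fa_specific", "fa_food")


def compose_queries(taxonomy: SearchTaxonomy,
                    profile: PlatformProfile) -> list[Query]:
    """Build the three per-platform queries: burn terms x one FA group each.

    Raises :class:`BudgetExceededError` naming the offending query if a
    rendered query exceeds the profile's character budget — queries are
    never silently truncated.
    """
    queries = []
    for fa in _FA_GROUPS:
        groups = [taxonomy.terms("burn_injury"), taxonomy.terms(fa)]
        if profile.include_children:
            groups.append(taxonomy.terms("children"))
        excluded = (taxonomy.terms("exclusion")
                    if profile.include_exclusions else ())
        q = Query(platform=profile.platform,
                  required_groups=tuple(tuple(g) for g in groups),
                  excluded_terms=tuple(excluded),
                  char_budget=profile.char_budget,
                  name=f"burn_injury+{fa}")
        rendered = render_query(q)
        if profile.char_budget is not None and len(rendered) > profile.char_budget:
            raise BudgetExceededError(
                f"query {q.name!r} for platform {profile.platform!r} renders "
                f"to {len(rendered)} characters, over the budget of "
                f"{profile.char_budget}")
        queries.append(q)
    return queries


def _quote(term: str) -> str:
    return f'"{term}"'


def render_query(query: Query) -> str:
    """Render as parenthesized OR-groups joined by AND, NOT-group for
    exclusions — the default search-engine dialect."""
    parts = ["(" + " OR ".join(_quote(t) for t in group) + ")"
             for group in query.required_groups]
    s = " AND ".join(parts)
    if query.excluded_terms:
        s += " AND NOT (" + " OR ".join(_quote(t) for t in query.excluded_terms) + ")"
    return s


_GROUP_RE = re.compile(r'(NOT\s+)?\(([^()]*)\)')


def parse_query(rendered: str, platform: str = "",
                char_budget: int | None = None) -> Query:
    """Inverse of :func:`render_query` on its own output."""
    groups: list[tuple[str, ...]] = []
    excluded: tuple[str, ...] = ()
    for m in _GROUP_RE.finditer(rendered):
        terms = tuple(t.strip().strip('"') for t in m.group(2).split(" OR "))
        if m.group(1):
            excluded = terms
        else:
            groups.append(terms)
    return Query(platform=platform, required_groups=tuple(groups),
                 excluded_terms=excluded, char_budget=char_budget)


# --- thread selection -------------------------------------------------------

def thread_matches(thread: Thread, queries: list[Query]) -> bool:
    texts = [thread.title] + [p.text for p in thread.posts]
    return any(match_text(text, q) for text in texts for q in queries)


def select_threads(threads: list[Thread], queries: list[Query]) -> list[Thread]:
    """Retain whole threads in which any post (or the title) matches any
    query; duplicates across queries or repeated ids are merged."""
    seen: set[str] = set()
    out = []
    for t in threads:
        if t.id in seen:
            continue
        if thread_matches(t, queries):
            seen.add(t.id)
            out.append(t)
    return out
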