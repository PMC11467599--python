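"""Text normalization: symbol/emoji stripping, tokenization, lemmatization.

Pipeline: strip emoji and punctuation -> casefold -> whitespace-tokenize ->
lemmatize -> drop stopwords. The lemmatizer is a compact rule-based English
lemmatizer (irregular-form table plus suffix rules guarded by the classic
consonant-vowel measure) frozen in this module so that results are
reproducible without any model download. It reduces plural nouns and
-ed/-ing verb forms to dictionary form; it is intentionally conservative
and leaves a token unchanged rather than over-stripping.

The whole pipeline is idempotent: preprocessing its own output returns it
unchanged (lemmas are fixpoints of the lemmatizer by construction).
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path


@dataclass
class TokenList:
    """Normalized tokens for one analysis unit."""

    tokens: list[str] = field(default_factory=list)
    source_post_id: str = ""

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self):
        return len(self.tokens)


# --- symbol and emoji stripping ---------------------------------------------

# Named emoji blocks: Emoticons (1F600-1F64F), Miscellaneous Symbols and
# Pictographs (1F300-1F5FF), Transport and Map Symbols (1F680-1F6FF),
# Supplemental Symbols and Pictographs (1F900-1F9FF). These all carry
# Unicode category So/Sk/Cf etc., so keeping only letters, digits and
# whitespace removes them together with all punctuation, variation
# selectors and zero-width joiners in one deterministic pass.

def _keep(ch: str) -> bool:
    if ch.isspace():
        return True
    return unicodedata.category(ch)[0] in ("L", "N")


def strip_symbols(text: str) -> str:
    """Remove emoji, pictographs, symbols and punctuation.

    Letters, digits and whitespace are preserved verbatim; no whitespace
    collapsing is performed (downstream tokenization splits on runs of
    whitespace anyway). Idempotent.
    """
    return "".join(ch for ch in text if _keep(ch))


# --- lemmatizer --------------------------------------------------------------

_VOWELS = "aeiou"

_IRREGULAR = {
    "burnt": "burn", "burned": "burn", "scalded": "scald",
    "sunburned": "sunburn", "sunburnt": "sunburn", "scalds": "scald",
    "children": "child", "kids": "kid", "babies": "baby",
    "calories": "calorie", "potatoes": "potato", "tomatoes": "tomato",
    "feet": "foot", "teeth": "tooth", "men": "man", "women": "woman",
    "people": "person", "mice": "mouse",
    "ran": "run", "running": "run", "went": "go", "gone": "go",
    "got": "get", "getting": "get", "said": "say", "saw": "see",
    "made": "make", "took": "take", "taken": "take", "gave": "give",
    "given": "give", "left": "leave", "felt": "feel", "kept": "keep",
    "put": "put", "told": "tell", "found": "find", "thought": "think",
    "better": "good", "best": "good", "worse": "bad", "worst": "bad",
    "frozen": "freeze", "froze": "freeze",
}


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Porter's m: the number of vowel-consonant sequences in the stem."""
    m = 0
    prev_cons = True
    for i in range(len(stem)):
        cons = _is_cons(stem, i)
        if cons and not prev_cons:
            m += 1
        prev_cons = cons
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_cvc(stem: str) -> bool:
    if len(stem) < 3:
        return False
    return (_is_cons(stem, len(stem) - 3)
            and not _is_cons(stem, len(stem) - 2)
            and _is_cons(stem, len(stem) - 1)
            and stem[-1] not in "wxy")


def _fixup(stem: str) -> str:
    """Measure-guarded fixups after removing -ed/-ing: undouble a trailing
    double consonant ("stopped" -> "stop") and restore the silent e on
    short CVC stems ("making" -> "make")."""
    if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in "lsz" \
            and _is_cons(stem, len(stem) - 1):
        return stem[:-1]
    if _measure(stem) == 1 and _ends_cvc(stem):
        return stem + "e"
    return stem


def _lemma_once(word: str) -> str:
    if word in _IRREGULAR:
        return _IRREGULAR[word]
    if len(word) < 4 or not word.isalpha():
        return word
    # plural nouns / 3rd-person verbs
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith(("ches", "shes", "xes", "zes")):
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    # past tense / progressive
    if word.endswith("ied") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("ed"):
        stem = word[:-2]
        if len(stem) >= 3 and _has_vowel(stem) and _measure(stem) > 0:
            return _fixup(stem)
        return word
    if word.endswith("ing"):
        stem = word[:-3]
        if len(stem) >= 3 and _has_vowel(stem):
            return _fixup(stem)
        return word
    return word


@lru_cache(maxsize=65536)
def lemmatize(word: str) -> str:
    """Dictionary form of a lowercase token; a fixpoint of itself."""
    current = word
    for _ in range(6):
        nxt = _lemma_once(current)
        if nxt == current:
            return current
        current = nxt
    return current


# --- stopwords and the full pipeline ----------------------------------------

def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load the frozen stopword list (one lowercase term per line)."""
    if path is None:
        text = resources.files("convomine.data").joinpath(
            "stopwords.txt").read_text()
    else:
        text = Path(path).read_text()
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def load_pronouns() -> frozenset[str]:
    text = resources.files("convomine.data").joinpath("pronouns.txt").read_text()
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


DEFAULT_STOPWORDS = load_stopwords()


def tokenize_lemmatize(text: str,
                       stopwords: frozenset[str] | None = None) -> list[str]:
    """Normalize raw text to lowercase lemma tokens, stopwords removed.

    Stopwords are filtered both on the surface form and on the lemma, so
    no output token is ever in the active stopword list. Numerals are
    retained ("20 minutes" is topically meaningful).
    """
    if stopwords is None:
        stopwords = DEFAULT_STOPWORDS
    out = []
    for tok in strip_symbols(text).casefold().split():
        if tok in stopwords:
            continue
        lemma = lemmatize(tok)
        if lemma and lemma not in stopwords:
            out.append(lemma)
    return out


def preprocess_post(text: str, post_id: str = "",
                    stopwords: frozenset[str] | None = None) -> TokenList:
    return TokenList(tokens=tokenize_lemmatize(text, stopwords),
                     source_post_id=post_id)
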