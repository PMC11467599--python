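"""Conversation-thread data model and NDJSON serialization.

A thread is one conversation unit: an initial post plus replies. Threads
are stored one-per-line as JSON objects (NDJSON), the interchange format
used by every pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass
class Post:
    """A single post, comment or tweet within a thread."""

    id: str
    text: str
    author: str = ""
    timestamp: str = ""  # ISO-8601; empty when unknown
    user_description: str = ""

    def to_dict(self) -> dict:
        d = {"id": self.id, "text": self.text, "author": self.author,
             "timestamp": self.timestamp}
        if self.user_description:
            d["user_description"] = self.user_description
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Post":
        return cls(
            id=str(d["id"]),
            text=d.get("text", ""),
            author=d.get("author", ""),
            timestamp=d.get("timestamp", ""),
            user_description=d.get("user_description", ""),
        )


@dataclass
class Thread:
    """An ordered conversation: title plus posts on one platform."""

    id: str
    platform: str
    posts: list[Post] = field(default_factory=list)
    title: str = ""

    @property
    def n_posts(self) -> int:
        return len(self.posts)

    @property
    def n_users(self) -> int:
        """Distinct contributing authors; anonymous posts each count once."""
        named = {p.author for p in self.posts if p.author}
        anonymous = sum(1 for p in self.posts if not p.author)
        return len(named) + anonymous

    def main_unit_text(self) -> str:
        """Title plus initial post — the forum analysis unit."""
        first = self.posts[0].text if self.posts else ""
        return f"{self.title} {first}".strip()

    def to_dict(self) -> dict:
        d = {"id": self.id, "platform": self.platform,
             "posts": [p.to_dict() for p in self.posts]}
        if self.title:
            d["title"] = self.title
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Thread":
        return cls(
            id=str(d["id"]),
            platform=d.get("platform", ""),
            posts=[Post.from_dict(p) for p in d.get("posts", [])],
            title=d.get("title", ""),
        )


def write_threads_ndjson(threads: Iterable[Thread], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for t in threads:
            fh.write(json.dumps(t.to_dict(), ensure_ascii=False,
                                sort_keys=True) + "\n")


def read_threads_ndjson(path: str | Path) -> Iterator[Thread]:
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield Thread.from_dict(json.loads(line))


def threads_to_ndjson_bytes(threads: Iterable[Thread]) -> bytes:
    """Serialize threads to the canonical NDJSON byte string (sorted keys)."""
    lines = [json.dumps(t.to_dict(), ensure_ascii=False, sort_keys=True)
             for t in threads]
    return ("\n".join(lines) + ("\n" if lines else "")).encode("utf-8")
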