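"""Compose and render the three boolean search queries for each platform
profile, and check them against the microblog 1024-character budget.

Writes results/queries.txt.
"""

from pathlib import Path

from convomine.lexicon import (FORUM_PROFILE, MICROBLOG_PROFILE,
                               VIDEO_COMMENTS_PROFILE, compose_queries,
                               default_taxonomy, render_query)

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    tax = default_taxonomy()
    lines = []
    for profile in (FORUM_PROFILE, MICROBLOG_PROFILE, VIDEO_COMMENTS_PROFILE):
        lines.append(f"## platform: {profile.platform} "
                     f"(unit: {profile.analysis_unit}, "
                     f"budget: {profile.char_budget or 'unlimited'})")
        for q in compose_queries(tax, profile):
            rendered = render_query(q)
            lines.append(f"# {q.name} ({len(rendered)} chars)")
            lines.append(rendered)
        lines.append("")
    text = "\n".join(lines)
    (OUT / "queries.txt").write_text(text)
    print(text)
    print("Each platform gets exactly 3 queries (burn terms x one first-aid "
          "group); the microblog variants stay within the 1024-character "
          "budget with child and exclusion groups attached.")


if __name__ == "__main__":
    main()
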