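"""End-to-end orchestration: synthesize/ingest -> search -> filter -> topics
-> characterize, with a run manifest recording counts at every stage.

The manifest carries the full config snapshot, the seed, per-stage
input/output counts and library versions — enough to re-run identically.
Identical config and seed reproduce identical outputs at every stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import sklearn

from . import __version__
from .characterize import build_report
from .embedding import EmbeddingModel, train_embeddings
from .io import Thread, write_threads_ndjson
from .lexicon import (PlatformProfile, SearchTaxonomy, compose_queries,
                      default_taxonomy, select_threads)
from .preprocess import tokenize_lemmatize
from .relevance import (ExpandedLexicon, calibrate_thresholds, expand_lexicon,
                        filter_corpus, negative_seed_terms,
                        positive_seed_terms, score_unit)
from .synth import GoldLabels, SynthConfig, generate_corpus, \
    generate_training_text
from .topics import assign_all, fit_topics, multi_topic_rate, top_words

_KIND_PROFILE = {
    "forum": dict(analysis_unit="title_plus_main_post"),
    "microblog": dict(analysis_unit="per_tweet", include_children=True,
                      include_exclusions=True, char_budget=1024),
    "video_comments": dict(analysis_unit="per_comment"),
}


@dataclass(frozen=True)
class PipelineConfig:
    synth: SynthConfig = SynthConfig()
    k_neighbors: int = 50
    dim: int = 50
    window: int = 5
    epochs: int = 5
    min_count: int = 2
    n_training_sentences: int = 4000
    negative_strategy: str = "exclusion_terms"  # or "negated_vectors"
    calibration_grid: int = 128
    topics_k: int = 11
    tau: float = 0.25
    top_n_words: int = 50

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    config: dict
    seed: int
    versions: dict
    stages: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def record(self, stage: str, platform: str, n_in: int, n_out: int):
        self.stages.append({"stage": stage, "platform": platform,
                            "n_in": int(n_in), "n_out": int(n_out)})

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


class StageError(RuntimeError):
    """A pipeline stage failed; carries the partial manifest."""

    def __init__(self, stage: str, cause: Exception, manifest: RunManifest):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest


def profile_for(platform: str, kind: str) -> PlatformProfile:
    return PlatformProfile(platform=platform, **_KIND_PROFILE[kind])


def _unit_gold(thread: Thread, gold: GoldLabels, unit: str):
    """Gold relevance per analysis unit: the initial post's label for whole
    threads, the post's own label otherwise."""
    if unit == "title_plus_main_post":
        first = thread.posts[0].id if thread.posts else None
        yield thread.main_unit_text(), bool(
            gold.post_relevance.get((thread.id, first), False))
    else:
        for p in thread.posts:
            yield p.text, bool(gold.post_relevance.get((thread.id, p.id), False))


def run_pipeline(config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> tuple[RunManifest, dict]:
    """Run every stage on a synthetic corpus; return (manifest, artifacts).

    Artifacts hold, per platform: selected and retained threads, the filter
    report, the topic model with top-word sheets, and the characterization
    report. Any stage error aborts with :class:`StageError` carrying the
    stage name and the partial manifest.
    """
    if config is None:
        config = PipelineConfig()
    manifest = RunManifest(
        config=config.to_dict(), seed=config.synth.seed,
        versions={"convomine": __version__, "numpy": np.__version__,
                  "scikit-learn": sklearn.__version__,
                  "pandas": pd.__version__})
    artifacts: dict = {"platforms": {}}
    taxonomy = default_taxonomy()
    stage = "synth"
    try:
        threads, gold = generate_corpus(config.synth, taxonomy)
        manifest.record("synth", "all", 0,
                        sum(t.n_posts for t in threads))
        artifacts["gold"] = gold
        artifacts["threads"] = threads

        stage = "embeddings"
        training = generate_training_text(
            config.synth, config.n_training_sentences, taxonomy)
        model = train_embeddings(
            training, dim=config.dim, window=config.window,
            epochs=config.epochs, seed=config.synth.seed,
            min_count=config.min_count)
        manifest.record("embeddings", "all", len(training), len(model.vocab))
        artifacts["embedding_model"] = model

        stage = "lexicons"
        pos = expand_lexicon(model, positive_seed_terms(taxonomy),
                             config.k_neighbors, "relevant")
        if config.negative_strategy == "negated_vectors":
            neg = expand_lexicon(model, positive_seed_terms(taxonomy),
                                 config.k_neighbors, "irrelevant", negate=True)
        else:
            neg = expand_lexicon(model, negative_seed_terms(taxonomy),
                                 config.k_neighbors, "irrelevant")
        artifacts["lexicons"] = {"positive": pos, "negative": neg}

        for spec in config.synth.platforms:
            plat = spec.platform
            profile = profile_for(plat, spec.kind)
            plat_threads = [t for t in threads if t.platform == plat]
            part: dict = {"profile": profile}
            artifacts["platforms"][plat] = part

            stage = f"search:{plat}"
            queries = compose_queries(taxonomy, profile)
            selected = select_threads(plat_threads, queries)
            manifest.record("search", plat, len(plat_threads), len(selected))
            part["selected"] = selected

            stage = f"calibrate:{plat}"
            scored = []
            for t in selected:
                for text, label in _unit_gold(t, gold, profile.analysis_unit):
                    s = score_unit(tokenize_lemmatize(text), pos, neg, model)
                    scored.append((s, label))
            labels = {lab for _, lab in scored}
            if len(labels) == 2:
                thr = calibrate_thresholds(scored, grid=config.calibration_grid,
                                           platform=plat)
                manifest.thresholds[plat] = {
                    "theta_pos": thr.theta_pos, "theta_neg": thr.theta_neg}
            else:
                thr = None  # degenerate sample: nothing to calibrate
            part["thresholds"] = thr

            stage = f"filter:{plat}"
            if thr is not None:
                retained, report = filter_corpus(
                    selected, profile, pos, neg, model, thr)
            else:
                retained, report = [], None
            manifest.record("filter", plat,
                            report.n_before if report else 0,
                            report.n_after if report else 0)
            part["retained"] = retained
            part["filter_report"] = report

            stage = f"topics:{plat}"
            if profile.analysis_unit == "title_plus_main_post":
                docs = [[tok for p in t.posts
                         for tok in tokenize_lemmatize(p.text)]
                        for t in retained]
                doc_ids = [t.id for t in retained]
            else:
                docs = [tokenize_lemmatize(p.text)
                        for t in retained for p in t.posts]
                doc_ids = [p.id for t in retained for p in t.posts]
            docs_ids = [(d, i) for d, i in zip(docs, doc_ids) if d]
            if docs_ids:
                kept_docs = [d for d, _ in docs_ids]
                kept_ids = [i for _, i in docs_ids]
                tm = fit_topics(kept_docs, K=config.topics_k,
                                seed=config.synth.seed, doc_ids=kept_ids)
                assignment = assign_all(tm, config.tau)
                part["topic_model"] = tm
                part["topic_assignment"] = assignment
                part["topic_top_words"] = {
                    k: top_words(tm, k, 20) for k in range(tm.K)}
                part["multi_topic_rate"] = multi_topic_rate(
                    assignment, len(kept_ids))
            else:
                part["topic_model"] = None
                part["topic_assignment"] = None
            manifest.record("topics", plat, len(docs), len(docs_ids))

            stage = f"characterize:{plat}"
            if retained:
                burn_records = [gold.burn_records[t.id] for t in retained
                                if t.id in gold.burn_records]
                token_corpus = [tokenize_lemmatize(p.text)
                                for t in retained for p in t.posts]
                prevalence_terms = (taxonomy.terms("fa_specific")
                                    + taxonomy.terms("fa_food"))
                by_user: dict[str, str] = {}
                for t in retained:
                    for p in t.posts:
                        if p.author and p.author not in by_user:
                            by_user[p.author] = p.user_description
                descriptions = [d for _, d in sorted(by_user.items()) if d]
                part["report"] = build_report(
                    retained, gold.thread_purpose, burn_records,
                    token_corpus, prevalence_terms, descriptions)
            else:
                part["report"] = None
            manifest.record("characterize", plat, len(retained),
                            len(retained))
    except Exception as exc:  # annotate with the failing stage
        raise StageError(stage, exc, manifest) from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest.save(outdir / "manifest.json")
        write_threads_ndjson(artifacts["threads"], outdir / "threads.ndjson")
    return manifest, artifacts
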