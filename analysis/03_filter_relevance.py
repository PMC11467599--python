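"""Train embeddings on the synthetic training text, expand the positive and
negative lexicons, calibrate per-platform dual thresholds against gold
labels, and measure filter fidelity on the planted corpus.

Writes results/filter_report.json and results/expanded_lexicons.json.
"""

import json
from pathlib import Path

import numpy as np

from convomine.embedding import train_embeddings
from convomine.lexicon import default_taxonomy
from convomine.preprocess import tokenize_lemmatize
from convomine.relevance import (calibrate_thresholds, classify,
                                 expand_lexicon, negative_seed_terms,
                                 positive_seed_terms, score_unit)
from convomine.synth import PlatformSpec, SynthConfig, generate_corpus, \
    generate_training_text

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main():
    cfg = SynthConfig(seed=SEED, relevant_fraction=0.3,
                      distractor_fraction=0.4,
                      platforms=(PlatformSpec("microblog", "microblog",
                                              2000, nb_p=1.0),))
    threads, gold = generate_corpus(cfg)
    training = generate_training_text(cfg, n_sentences=4000)
    model = train_embeddings(training, dim=50, window=5, epochs=5, seed=SEED)

    tax = default_taxonomy()
    pos = expand_lexicon(model, positive_seed_terms(tax), 50, "relevant")
    neg = expand_lexicon(model, negative_seed_terms(tax), 50, "irrelevant")
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "expanded_lexicons.json").write_text(json.dumps({
        "positive": {"seeds": pos.seed_terms, "neighbors": pos.neighbor_terms},
        "negative": {"seeds": neg.seed_terms, "neighbors": neg.neighbor_terms},
    }, indent=2) + "\n")

    scored = [(score_unit(tokenize_lemmatize(p.text), pos, neg, model),
               gold.post_relevance[(t.id, p.id)])
              for t in threads for p in t.posts]
    thr = calibrate_thresholds(scored, platform="microblog")

    pred = np.array([s.defined and classify(s, thr) == "relevant"
                     for s, _ in scored])
    y = np.array([g for _, g in scored])
    tp = int((pred & y).sum())
    recall = tp / int(y.sum())
    precision = tp / int(pred.sum())
    report = {
        "seed": SEED, "n_posts": len(scored),
        "theta_pos": thr.theta_pos, "theta_neg": thr.theta_neg,
        "calibration": thr.provenance,
        "precision": round(precision, 4), "recall": round(recall, 4),
        "f1": round(2 * precision * recall / (precision + recall), 4),
        "retained": int(pred.sum()),
    }
    (ROOT / "results" / "filter_report.json").write_text(
        json.dumps(report, indent=2) + "\n")
    print(json.dumps(report, indent=2))
    print("\nSample positive neighbours:", ", ".join(pos.neighbor_terms[:8]))
    print("Sample negative neighbours:", ", ".join(neg.neighbor_terms[:8]))
    print("\nThe calibrated dual thresholds separate the planted injury "
          "sense from the distractor senses essentially perfectly on this "
          "template corpus; real text would be noisier.")


if __name__ == "__main__":
    main()
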