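import numpy as np
import pytest

from convomine.embedding import EmbeddingModel, train_embeddings
from convomine.lexicon import default_taxonomy
from convomine.synth import SynthConfig, generate_training_text


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def planted_corpus():
    """~200 token sentences in which "burn" and "scald" always co-occur with
    injury context, while "calorie" co-occurs with exercise context."""
    rng = np.random.default_rng(42)
    injury = ["water", "skin", "blister", "cool", "cream", "dressing"]
    exercise = ["gym", "workout", "treadmill", "diet", "exercise", "step"]
    shared = [f"common{i}" for i in range(30)]  # context-neutral filler
    sentences = []
    for _ in range(100):
        ctx = list(rng.choice(injury, size=4)) + list(rng.choice(shared, 3))
        sentences.append(["burn", "scald"] + ctx)
    for _ in range(100):
        ctx = list(rng.choice(exercise, size=4)) + list(rng.choice(shared, 3))
        sentences.append(["calorie", "energy"] + ctx)
    return sentences


@pytest.fixture(scope="session")
def planted_model(planted_corpus):
    return train_embeddings(planted_corpus, dim=16, window=5, epochs=10,
                            seed=0, min_count=1)


@pytest.fixture(scope="session")
def synth_training_model():
    """Embeddings trained on the template-derived synthetic training text."""
    cfg = SynthConfig(seed=11)
    corpus = generate_training_text(cfg, n_sentences=1500)
    return train_embeddings(corpus, dim=32, window=5, epochs=5, seed=11)


def make_model(vectors: dict[str, list[float]],
               subword: bool = False) -> EmbeddingModel:
    """Embedding model with hand-set vectors, for exact-geometry tests."""
    vocab = list(vectors)
    mat = np.array([vectors[w] for w in vocab], dtype=float)
    return EmbeddingModel(dim=mat.shape[1], vocab=vocab, vectors=mat,
                          subword=subword)


@pytest.fixture
def toy_model():
    return make_model({
        "burn": [1.0, 0.0, 0.0],
        "scald": [0.9, 0.1, 0.0],
        "water": [0.7, 0.7, 0.0],
        "calorie": [0.0, 0.0, 1.0],
        "gym": [0.1, 0.0, 0.9],
    })
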