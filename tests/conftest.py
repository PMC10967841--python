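import numpy as np
import pytest

from regionspace.model import TrainConfig, split_corpus, train
from regionspace.synthetic import SyntheticCorpusConfig, generate_corpus_documents
from regionspace.universe import Document, build_universe


@pytest.fixture(scope="session")
def default_corpus():
    """The reference synthetic condition: 320 documents over 2000 tiles."""
    cfg = SyntheticCorpusConfig()
    documents, signatures, universe = generate_corpus_documents(cfg)
    return cfg, documents, signatures, universe


@pytest.fixture(scope="session")
def default_split(default_corpus):
    cfg, documents, _, _ = default_corpus
    return split_corpus(documents, seed=cfg.seed)


@pytest.fixture(scope="session")
def antibody_model(default_corpus, default_split):
    cfg, _, _, universe = default_corpus
    train_core, val, _ = default_split
    config = TrainConfig(seed=cfg.seed, label_types_used=("antibody",))
    return train(train_core, val, universe, config)


@pytest.fixture(scope="session")
def combined_model(default_corpus, default_split):
    cfg, _, _, universe = default_corpus
    train_core, val, _ = default_split
    config = TrainConfig(seed=cfg.seed, label_types_used=("antibody", "cell_type"))
    return train(train_core, val, universe, config)


@pytest.fixture(scope="session")
def toy_corpus():
    """Two perfectly separable antibody classes with disjoint 20-tile
    signatures, 10 documents each, no background noise."""
    universe = build_universe({"chrT": 60_000}, 1000)
    rng = np.random.default_rng(11)
    sig = {"a": list(range(0, 20)), "b": list(range(20, 40))}
    docs = []
    for label, tiles in sig.items():
        for i in range(10):
            tokens = tuple(int(t) for t in rng.choice(tiles, size=15, replace=False))
            docs.append(
                Document(id=f"{label}{i}", tokens=tokens, labels={"antibody": label})
            )
    return universe, docs, sig


@pytest.fixture(scope="session")
def toy_model(toy_corpus):
    universe, docs, _ = toy_corpus
    train_docs = [d for d in docs if not d.id.endswith(("8", "9"))]
    val_docs = [d for d in docs if d.id.endswith(("8", "9"))]
    config = TrainConfig(d=16, k=1, epochs=30, patience=5, seed=3,
                         label_types_used=("antibody",))
    return train(train_docs, val_docs, universe, config), train_docs, val_docs
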