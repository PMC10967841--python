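"""Joint embedding of tokenized region sets and metadata labels.

The model learns a single dictionary ``D`` (a D x d matrix) of d-dimensional
embeddings, one row per feature, where features are the universe tiles plus
the metadata labels.  An entity — a region-set document (bag of tile features)
or a label (single feature) — is embedded by pooling its feature rows.  The
training objective pulls each document towards the labels annotating it and
away from k sampled negative labels, through a softmax negative-log-likelihood
over cosine similarities:

    loss = -log( exp(s(a, b+)) / (exp(s(a, b+)) + sum_i exp(s(a, b_i-))) )

where ``a`` is a document, ``b+`` one of its labels, ``b_1- .. b_k-`` labels of
the same type not annotating it, and ``s`` is cosine similarity.  Optimization
is plain per-pair SGD with early stopping on validation loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .universe import Document, Universe, label_feature, normalize_label

log = logging.getLogger(__name__)

__all__ = [
    "EmbeddingDictionary",
    "TrainConfig",
    "TrainedModel",
    "init_dictionary",
    "embed_entity",
    "cosine_similarity",
    "softmax_nll_loss",
    "pair_gradients",
    "sample_negatives",
    "split_corpus",
    "build_vocab",
    "train",
]


@dataclass
class EmbeddingDictionary:
    """The D x d feature-embedding table: one row per vocabulary feature."""

    vocab: list[str]
    matrix: np.ndarray  # shape (D, d), float64

    def __post_init__(self) -> None:
        if len(self.vocab) != self.matrix.shape[0]:
            raise ValueError("vocab length does not match matrix rows")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite entries in embedding matrix")
        self._index = {name: i for i, name in enumerate(self.vocab)}
        if len(self._index) != len(self.vocab):
            raise ValueError("duplicate feature names in vocabulary")

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.vocab)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        return self._index[name]

    def row(self, name: str) -> np.ndarray:
        return self.matrix[self._index[name]]

    def copy(self) -> "EmbeddingDictionary":
        return EmbeddingDictionary(list(self.vocab), self.matrix.copy())


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the embedding model.

    d            embedding dimension
    k            negative labels sampled per positive pair
    lr           SGD learning rate
    epochs       maximum number of passes over the training pairs
    patience     early-stopping patience in epochs of non-improving
                 validation loss
    seed         RNG seed controlling init, shuffling and negative sampling
    aggregation  entity pooling: "mean" (default; keeps entity norms
                 comparable across region sets of very different sizes) or
                 "sum" (the literal StarSpace formulation)
    label_types_used  which metadata label types participate in training;
                 a single type gives a single-label model, several give the
                 combined model
    """

    d: int = 100
    k: int = 10
    lr: float = 0.05
    epochs: int = 50
    patience: int = 5
    seed: int = 0
    aggregation: str = "mean"
    label_types_used: tuple[str, ...] = ("antibody",)

    def __post_init__(self) -> None:
        if self.d < 2:
            raise ValueError("embedding dimension d must be >= 2")
        if self.k < 1:
            raise ValueError("k (negatives per positive) must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        object.__setattr__(
            self,
            "label_types_used",
            tuple(normalize_label(t) for t in self.label_types_used),
        )


def init_dictionary(vocab: Sequence[str], d: int, seed: int) -> EmbeddingDictionary:
    """Initialize a dictionary with rows i.i.d. uniform on [-1/d, 1/d]."""
    vocab = list(vocab)
    if not vocab:
        raise ValueError("empty vocabulary")
    rng = np.random.default_rng(seed)
    matrix = rng.uniform(-1.0 / d, 1.0 / d, size=(len(vocab), d))
    return EmbeddingDictionary(vocab, matrix)


def embed_entity(
    features: Sequence[int], matrix: np.ndarray, aggregation: str = "mean"
) -> np.ndarray:
    """Pool the dictionary rows of a feature bag into one d-vector."""
    if len(features) == 0:
        raise ValueError("no in-vocabulary features to embed")
    rows = matrix[np.asarray(features, dtype=np.intp)]
    return rows.mean(axis=0) if aggregation == "mean" else rows.sum(axis=0)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate embedding: zero vector has no direction")
    return float(np.dot(u, v) / (nu * nv))


def softmax_nll_loss(s_pos: float, s_negs: Sequence[float]) -> float:
    """Negative log softmax probability of the positive similarity.

    Equals log(k+1) when all k+1 similarities coincide, and tends to 0 as the
    positive similarity dominates.  Computed via log-sum-exp for stability.
    """
    if len(s_negs) == 0:
        raise ValueError("at least one negative similarity is required")
    scores = np.concatenate(([s_pos], np.asarray(s_negs, dtype=float)))
    return float(logsumexp(scores) - s_pos)


def pair_gradients(
    matrix: np.ndarray,
    token_rows: Sequence[int],
    label_rows: Sequence[int],
    aggregation: str = "mean",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss and analytic gradients for one (document, positive, negatives) pair.

    ``label_rows[0]`` is the positive label row, the rest are negatives.

    Returns ``(loss, grad_token_row, grad_label_rows)`` where
    ``grad_token_row`` is the gradient shared by every token row of the
    document (identical because the entity embedding is a symmetric pool) and
    ``grad_label_rows`` has one gradient row per entry of ``label_rows``.
    """
    tok = np.asarray(token_rows, dtype=np.intp)
    lab = np.asarray(label_rows, dtype=np.intp)
    u = embed_entity(tok, matrix, aggregation)
    V = matrix[lab]  # (m, d); row 0 positive
    nu = np.linalg.norm(u)
    nV = np.linalg.norm(V, axis=1)
    if nu == 0.0 or np.any(nV == 0.0):
        raise ValueError("degenerate embedding: zero vector has no direction")
    s = V @ u / (nV * nu)
    loss = float(logsumexp(s) - s[0])
    p = np.exp(s - logsumexp(s))
    g = p.copy()
    g[0] -= 1.0  # d loss / d s_j
    # chain through cosine: ds_j/du = V_j/(nu nV_j) - s_j u/nu^2
    du = (g / nV) @ V / nu - float(g @ s) * u / nu**2
    dV = (g / (nV * nu))[:, None] * u[None, :] - ((g * s) / nV**2)[:, None] * V
    if aggregation == "mean":
        du = du / len(tok)
    return loss, du, dV


def sample_negatives(
    label_pool: Iterable[str],
    document_labels: Iterable[str],
    k: int,
    rng: np.random.Generator,
) -> list[str]:
    """Sample k negative labels uniformly without replacement.

    Eligible negatives are pool labels not associated with the document.  If
    fewer than k exist, all of them are returned (effective k reduced).
    """
    excluded = set(document_labels)
    eligible = sorted(set(label_pool) - excluded)
    if not eligible:
        raise ValueError("degenerate label pool: no eligible negative label")
    if len(eligible) <= k:
        if len(eligible) < k:
            log.debug("only %d eligible negatives for k=%d", len(eligible), k)
        return list(eligible)
    idx = rng.choice(len(eligible), size=k, replace=False)
    return [eligible[i] for i in idx]


def split_corpus(
    documents: Sequence[Document],
    test_frac: float = 0.15,
    val_frac_of_train: float = 0.10,
    seed: int = 0,
) -> tuple[list[Document], list[Document], list[Document]]:
    """Shuffle and split a corpus into (train_core, validation, test).

    |test| = floor(test_frac * N); |validation| = floor(val_frac_of_train *
    (N - |test|)); the remainder is the core training set.  The three parts
    are disjoint and exhaustive, and membership is fully determined by seed.
    """
    n = len(documents)
    if n < 3:
        raise ValueError("need at least 3 documents to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(test_frac * n)
    n_val = int(val_frac_of_train * (n - n_test))
    test = [documents[i] for i in order[:n_test]]
    val = [documents[i] for i in order[n_test : n_test + n_val]]
    train_core = [documents[i] for i in order[n_test + n_val :]]
    if not test or not val or not train_core:
        raise ValueError(
            f"degenerate split for N={n}: sizes "
            f"(train={len(train_core)}, val={len(val)}, test={len(test)})"
        )
    return train_core, val, test


def build_vocab(
    universe: Universe,
    documents: Sequence[Document],
    label_types: Sequence[str],
) -> list[str]:
    """Vocabulary: every universe tile, then every observed label feature.

    Tile features occupy rows 0 .. n_tiles-1 in token-id order, so a
    document's token ids are directly its dictionary row indices.  Label
    features follow in sorted order.
    """
    labels = sorted(
        {
            label_feature(t, doc.labels[t])
            for doc in documents
            for t in label_types
            if t in doc.labels
        }
    )
    return [universe.feature_name(i) for i in range(universe.n_tiles)] + labels


@dataclass
class TrainedModel:
    """A trained dictionary plus everything needed to embed new queries."""

    dictionary: EmbeddingDictionary
    universe: Universe
    config: TrainConfig
    training_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.universe.n_tiles > len(self.dictionary):
            raise ValueError("dictionary has fewer rows than universe tiles")

    @property
    def n_tiles(self) -> int:
        return self.universe.n_tiles

    def label_values(self, label_type: str) -> list[str]:
        """Label values of one type present in the model vocabulary."""
        prefix = normalize_label(label_type) + ":"
        return [
            name[len(prefix) :]
            for name in self.dictionary.vocab[self.n_tiles :]
            if name.startswith(prefix)
        ]

    @property
    def label_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for name in self.dictionary.vocab[self.n_tiles :]:
            seen.setdefault(name.split(":", 1)[0])
        return list(seen)

    def embed_document(self, doc: Document) -> np.ndarray:
        """Embed a document, dropping out-of-vocabulary tokens.

        Tokens outside the model's universe (possible when a query was
        tokenized against a different universe) are dropped with a logged
        count; a document with no in-vocabulary token raises.
        """
        in_vocab = [t for t in doc.tokens if 0 <= t < self.n_tiles]
        dropped = len(doc.tokens) - len(in_vocab)
        if dropped:
            log.warning("document %s: dropped %d out-of-vocabulary tokens", doc.id, dropped)
        if not in_vocab:
            raise ValueError(f"no in-vocabulary features in document {doc.id!r}")
        return embed_entity(in_vocab, self.dictionary.matrix, self.config.aggregation)

    def label_vector(self, label_type: str, value: str) -> np.ndarray:
        return self.dictionary.row(label_feature(label_type, value))


def _training_pairs(
    documents: Sequence[Document], label_types: Sequence[str]
) -> list[tuple[int, str, str]]:
    """(document index, label type, positive label feature) triples."""
    pairs = []
    for i, doc in enumerate(documents):
        for t in label_types:
            if t in doc.labels:
                pairs.append((i, t, label_feature(t, doc.labels[t])))
    return pairs


def _mean_corpus_loss(
    matrix: np.ndarray,
    documents: Sequence[Document],
    pairs: Sequence[tuple[int, str, str]],
    pools: Mapping[str, list[str]],
    dictionary: EmbeddingDictionary,
    config: TrainConfig,
    rng: np.random.Generator,
) -> float:
    total = 0.0
    for doc_i, ltype, pos in pairs:
        doc = documents[doc_i]
        negs = sample_negatives(pools[ltype], [pos], config.k, rng)
        rows = [dictionary.index(pos)] + [dictionary.index(nm) for nm in negs]
        loss, _, _ = pair_gradients(matrix, doc.tokens, rows, config.aggregation)
        total += loss
    return total / len(pairs)


def train(
    train_documents: Sequence[Document],
    validation_documents: Sequence[Document],
    universe: Universe,
    config: TrainConfig,
) -> TrainedModel:
    """Fit the joint document/label embedding dictionary by per-pair SGD.

    Every (document, associated label) pair of each used label type yields one
    SGD update per epoch: the positive label is contrasted against k labels of
    the same type not annotating the document, and the softmax NLL gradient is
    applied to the document's token rows, the positive row and the negative
    rows.  After each epoch the mean loss on the validation documents is
    computed with negatives drawn from a fixed validation seed (so the curve
    is comparable across epochs); training stops at ``epochs`` or after
    ``patience`` epochs without validation improvement, returning the
    dictionary of the best validation epoch.
    """
    types = config.label_types_used
    for doc in train_documents:
        if not any(t in doc.labels for t in types):
            raise ValueError(
                f"document {doc.id!r} has no label of the used types {types}"
            )

    all_docs = list(train_documents) + list(validation_documents)
    vocab = build_vocab(universe, all_docs, types)
    ss = np.random.SeedSequence(config.seed)
    init_ss, train_ss, val_ss = ss.spawn(3)
    dictionary = init_dictionary(vocab, config.d, init_ss)
    matrix = dictionary.matrix

    pools: dict[str, list[str]] = {
        t: sorted(
            {label_feature(t, d.labels[t]) for d in all_docs if t in d.labels}
        )
        for t in types
    }
    train_pairs = _training_pairs(train_documents, types)
    val_pairs = _training_pairs(validation_documents, types)
    if not train_pairs:
        raise ValueError("no usable (document, label) training pairs")

    rng = np.random.default_rng(train_ss)
    lr = config.lr
    best_val = np.inf
    best_matrix = matrix.copy()
    best_epoch = -1
    training_log: list[dict] = []
    since_improvement = 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(train_pairs))
        epoch_loss = 0.0
        for pi in order:
            doc_i, ltype, pos = train_pairs[pi]
            doc = train_documents[doc_i]
            negs = sample_negatives(pools[ltype], [pos], config.k, rng)
            rows = [dictionary.index(pos)] + [dictionary.index(nm) for nm in negs]
            loss, d_tok, d_lab = pair_gradients(
                matrix, doc.tokens, rows, config.aggregation
            )
            if not np.isfinite(loss):
                raise ValueError(
                    "divergence: non-finite training loss; try a lower lr"
                )
            epoch_loss += loss
            matrix[np.asarray(doc.tokens, dtype=np.intp)] -= lr * d_tok
            matrix[np.asarray(rows, dtype=np.intp)] -= lr * d_lab
        train_loss = epoch_loss / len(train_pairs)
        val_loss = (
            _mean_corpus_loss(
                matrix,
                validation_documents,
                val_pairs,
                pools,
                dictionary,
                config,
                np.random.default_rng(val_ss),
            )
            if val_pairs
            else train_loss
        )
        training_log.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        log.info("epoch %d: train loss %.6f, val loss %.6f", epoch, train_loss, val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_matrix = matrix.copy()
            best_epoch = epoch
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= config.patience:
                log.info("early stop at epoch %d (best epoch %d)", epoch, best_epoch)
                break

    final = EmbeddingDictionary(vocab, best_matrix)
    return TrainedModel(
        dictionary=final,
        universe=universe,
        config=config,
        training_log=training_log,
    )
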