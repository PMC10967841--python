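"""Embedding dictionary, loss, gradients, splitting and training."""

import math

import numpy as np
import pytest

from regionspace.model import (
    TrainConfig,
    cosine_similarity,
    embed_entity,
    init_dictionary,
    pair_gradients,
    sample_negatives,
    softmax_nll_loss,
    split_corpus,
    train,
)
from regionspace.retrieval import annotate_region_set
from regionspace.universe import Document


class TestInitDictionary:
    def test_reproducible_and_bounded(self):
        vocab = [f"f{i}" for i in range(10)]
        d1 = init_dictionary(vocab, 5, seed=42)
        d2 = init_dictionary(vocab, 5, seed=42)
        assert np.array_equal(d1.matrix, d2.matrix)
        assert d1.matrix.shape == (10, 5)
        assert np.all(np.abs(d1.matrix) <= 1 / 5)

    def test_duplicate_feature_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            init_dictionary(["a", "b", "a"], 4, seed=0)

    def test_empty_vocab_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            init_dictionary([], 4, seed=0)


class TestEmbedEntity:
    matrix = np.array([[1.0, 0.0], [0.0, 1.0]])

    def test_singleton_is_its_row(self):
        assert np.array_equal(embed_entity([0], self.matrix), self.matrix[0])

    def test_sum_vs_mean(self):
        assert np.allclose(embed_entity([0, 1], self.matrix, "sum"), [1, 1])
        assert np.allclose(embed_entity([0, 1], self.matrix, "mean"), [0.5, 0.5])

    def test_empty_bag_is_an_error(self):
        with pytest.raises(ValueError, match="no in-vocabulary features"):
            embed_entity([], self.matrix)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(30, 8))
        toks = [3, 17, 5, 22, 9]
        perm = [9, 5, 3, 22, 17]
        assert np.allclose(embed_entity(toks, m), embed_entity(perm, m))


class TestCosine:
    @pytest.mark.parametrize(
        "u, v, expected",
        [([1, 0], [1, 0], 1.0), ([1, 0], [0, 1], 0.0), ([1, 1], [1, 0], 1 / math.sqrt(2))],
    )
    def test_closed_forms(self, u, v, expected):
        assert cosine_similarity(np.array(u, float), np.array(v, float)) == pytest.approx(expected)

    def test_zero_vector_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate embedding"):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestSoftmaxLoss:
    def test_symmetric_case_is_log2(self):
        assert softmax_nll_loss(0.3, [0.3]) == pytest.approx(math.log(2))

    def test_equal_similarities_give_log_k_plus_1(self):
        for k in (1, 3, 7):
            assert softmax_nll_loss(0.5, [0.5] * k) == pytest.approx(math.log(k + 1))

    def test_frozen_value(self):
        # independent closed form: -log(e / (e + 2))
        assert softmax_nll_loss(1.0, [0.0, 0.0]) == pytest.approx(0.551445, abs=1e-6)

    def test_dominant_positive_drives_loss_to_zero(self):
        assert softmax_nll_loss(50.0, [0.0, 1.0]) < 1e-6

    def test_loss_nonnegative(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            s = rng.normal(size=4)
            assert softmax_nll_loss(s[0], s[1:]) >= 0

    def test_no_negatives_is_an_error(self):
        with pytest.raises(ValueError):
            softmax_nll_loss(1.0, [])


def _numeric_row_gradients(matrix, tokens, labels, aggregation, h=1e-6):
    """Central finite differences through the public loss composition."""

    def loss_of(m):
        u = embed_entity(tokens, m, aggregation)
        sims = [cosine_similarity(u, m[r]) for r in labels]
        return softmax_nll_loss(sims[0], sims[1:])

    touched = list(dict.fromkeys(list(tokens) + list(labels)))
    grads = {}
    for r in touched:
        g = np.zeros(matrix.shape[1])
        for j in range(matrix.shape[1]):
            m = matrix.copy()
            m[r, j] += h
            up = loss_of(m)
            m[r, j] -= 2 * h
            down = loss_of(m)
            g[j] = (up - down) / (2 * h)
        grads[r] = g
    return grads


@pytest.mark.parametrize("aggregation", ["mean", "sum"])
def test_analytic_gradients_match_finite_differences(aggregation):
    rng = np.random.default_rng(5)
    for _ in range(20):
        d = int(rng.integers(2, 9))
        k = int(rng.integers(1, 5))
        n_rows = 12
        matrix = rng.normal(scale=0.5, size=(n_rows, d))
        tokens = list(rng.choice(6, size=int(rng.integers(1, 5)), replace=False))
        labels = list(6 + rng.choice(6, size=k + 1, replace=False))
        loss, d_tok, d_lab = pair_gradients(matrix, tokens, labels, aggregation)
        numeric = _numeric_row_gradients(matrix, tokens, labels, aggregation)
        for t in tokens:
            assert np.allclose(d_tok, numeric[t], rtol=1e-5, atol=1e-7)
        for i, r in enumerate(labels):
            assert np.allclose(d_lab[i], numeric[r], rtol=1e-5, atol=1e-7)


class TestSampleNegatives:
    def test_forced_complement(self):
        rng = np.random.default_rng(0)
        assert set(sample_negatives(["a", "b", "c"], ["a"], 2, rng)) == {"b", "c"}

    def test_capped_at_pool(self):
        rng = np.random.default_rng(0)
        assert sample_negatives(["a", "b"], ["a"], 5, rng) == ["b"]

    def test_exhausted_pool_is_an_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="degenerate label pool"):
            sample_negatives(["a"], ["a"], 1, rng)

    def test_never_returns_document_labels(self):
        rng = np.random.default_rng(2)
        pool = [f"l{i}" for i in range(10)]
        for _ in range(50):
            negs = sample_negatives(pool, ["l3", "l7"], 4, rng)
            assert len(negs) == 4 and not {"l3", "l7"} & set(negs)


class TestSplitCorpus:
    def _docs(self, n):
        return [Document(id=f"d{i}", tokens=(i,), labels={"antibody": "x"}) for i in range(n)]

    @pytest.mark.parametrize("n, sizes", [(100, (77, 8, 15)), (20, (16, 1, 3))])
    def test_floor_rule_sizes(self, n, sizes):
        tr, va, te = split_corpus(self._docs(n), seed=0)
        assert (len(tr), len(va), len(te)) == sizes

    def test_disjoint_exhaustive_and_seeded(self):
        docs = self._docs(50)
        a = split_corpus(docs, seed=9)
        b = split_corpus(docs, seed=9)
        ids = lambda parts: [sorted(d.id for d in p) for p in parts]
        assert ids(a) == ids(b)
        all_ids = sorted(i for p in a for d in p for i in [d.id])
        assert all_ids == sorted(d.id for d in docs)
        c = split_corpus(docs, seed=10)
        assert ids(a) != ids(c)  # different shuffle

    def test_too_small_corpus(self):
        with pytest.raises(ValueError):
            split_corpus(self._docs(2))


class TestTraining:
    def test_validation_loss_improves_on_separable_toy(self, toy_corpus, toy_model):
        universe, docs, _ = toy_corpus
        model, train_docs, val_docs = toy_model
        log = model.training_log
        assert len(log) >= 2
        assert min(r["val_loss"] for r in log) < log[0]["val_loss"]
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_separable_toy_reaches_perfect_training_accuracy(self, toy_model):
        model, train_docs, _ = toy_model
        correct = 0
        for doc in train_docs:
            ann = annotate_region_set(doc, model)
            correct += ann.top("antibody") == doc.labels["antibody"]
        assert correct == len(train_docs)

    def test_training_is_deterministic(self, toy_corpus):
        universe, docs, _ = toy_corpus
        cfg = TrainConfig(d=8, k=1, epochs=5, patience=5, seed=21,
                          label_types_used=("antibody",))
        m1 = train(docs[:16], docs[16:], universe, cfg)
        m2 = train(docs[:16], docs[16:], universe, cfg)
        assert m1.training_log == m2.training_log
        assert np.array_equal(m1.dictionary.matrix, m2.dictionary.matrix)

    def test_unlabeled_document_is_named_in_error(self, toy_corpus):
        universe, docs, _ = toy_corpus
        bad = Document(id="nolabel", tokens=(1, 2), labels={})
        cfg = TrainConfig(d=8, k=1, epochs=2, label_types_used=("antibody",))
        with pytest.raises(ValueError, match="nolabel"):
            train(list(docs[:5]) + [bad], docs[16:], universe, cfg)

    def test_colocation_objective_on_default_corpus(self, antibody_model, default_split):
        """After training, >=90% of training documents are closest to their
        own antibody label among all antibody labels."""
        model = antibody_model
        train_core, _, _ = default_split
        hits = 0
        for doc in train_core:
            ann = annotate_region_set(doc, model)
            hits += ann.top("antibody") == doc.labels["antibody"]
        assert hits / len(train_core) >= 0.9


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(d=1)
    with pytest.raises(ValueError):
        TrainConfig(k=0)
    with pytest.raises(ValueError):
        TrainConfig(lr=0)
    with pytest.raises(ValueError):
        TrainConfig(aggregation="max")
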