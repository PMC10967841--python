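"""The three retrieval scenarios and their ranking contracts."""

import numpy as np
import pytest

from regionspace.model import EmbeddingDictionary, TrainConfig, TrainedModel
from regionspace.retrieval import (
    annotate_region_set,
    embed_database,
    retrieve_region_sets_by_label,
    retrieve_similar_region_sets,
)
from regionspace.universe import Document, Interval, build_universe


def _manual_model(label_rows: dict[str, np.ndarray], n_tiles=4, d=3, tile_matrix=None):
    """A hand-built model over a 4-tile universe with given label rows."""
    universe = build_universe({"chrA": n_tiles * 1000}, 1000)
    vocab = [universe.feature_name(i) for i in range(n_tiles)] + sorted(label_rows)
    if tile_matrix is None:
        rng = np.random.default_rng(0)
        tile_matrix = rng.normal(size=(n_tiles, d))
    matrix = np.vstack([tile_matrix] + [label_rows[k][None, :] for k in sorted(label_rows)])
    dictionary = EmbeddingDictionary(vocab, matrix.astype(float))
    cfg = TrainConfig(d=d, label_types_used=("antibody",))
    return TrainedModel(dictionary=dictionary, universe=universe, config=cfg)


class TestEmbedDatabase:
    def test_cardinality_and_determinism(self, toy_model, toy_corpus):
        model, train_docs, _ = toy_model
        db = embed_database(train_docs[:3], model)
        assert sorted(db) == sorted(d.id for d in train_docs[:3])
        again = embed_database(train_docs[:3], model)
        for k in db:
            assert np.array_equal(db[k], again[k])

    def test_all_oov_document_excluded(self, toy_model):
        model, train_docs, _ = toy_model
        oov = Document(id="oov", tokens=(10**6,), labels={})
        db = embed_database(list(train_docs[:2]) + [oov], model)
        assert "oov" not in db and len(db) == 2

    def test_empty_database_is_an_error(self, toy_model):
        model, _, _ = toy_model
        with pytest.raises(ValueError, match="empty database"):
            embed_database([], model)


class TestScenario1:
    def test_identity_match_ranks_first_with_similarity_one(self):
        model = _manual_model({"antibody:x": np.array([1.0, 2.0, 3.0])})
        db = {
            "match": np.array([2.0, 4.0, 6.0]),  # colinear with label row
            "other": np.array([-1.0, 0.5, 0.0]),
        }
        res = retrieve_region_sets_by_label("x", db, model)
        assert res.entries[0][0] == "match"
        assert res.entries[0][1] == pytest.approx(1.0)

    def test_r_clamps_to_database(self):
        model = _manual_model({"antibody:x": np.ones(3)})
        db = {f"d{i}": np.random.default_rng(i).normal(size=3) for i in range(4)}
        res = retrieve_region_sets_by_label("x", db, model, r=100)
        assert len(res.entries) == 4
        sims = res.similarities
        assert sims == sorted(sims, reverse=True)

    def test_ties_broken_by_ascending_id(self):
        model = _manual_model({"antibody:x": np.array([1.0, 0.0, 0.0])})
        v = np.array([3.0, 0.0, 0.0])
        db = {"b": v, "a": v.copy(), "c": v * 2}
        res = retrieve_region_sets_by_label("x", db, model)
        assert res.ids == ["a", "b", "c"]

    def test_unknown_label_suggests_near_strings(self):
        model = _manual_model({"antibody:h3k4me3": np.ones(3)})
        with pytest.raises(KeyError, match="h3k4me3"):
            retrieve_region_sets_by_label("h3k4me33", {"d": np.ones(3)}, model)

    def test_separable_corpus_returns_own_documents_on_top(self, toy_model):
        model, train_docs, _ = toy_model
        db = embed_database(train_docs, model)
        n_a = sum(d.labels["antibody"] == "a" for d in train_docs)
        res = retrieve_region_sets_by_label("a", db, model, r=n_a)
        assert all(doc_id.startswith("a") for doc_id in res.ids)


class TestScenario2:
    def test_confidence_arithmetic_and_threshold(self):
        # label rows engineered to give the query (token 0, vector e1)
        # similarities 0.9 / 0.75 to the two antibody labels
        def row(sim):
            return np.array([sim, np.sqrt(1 - sim**2), 0.0])

        tiles = np.eye(3)[[0, 0, 0]]
        tiles = np.vstack([tiles, np.eye(3)[0][None, :]])
        model = _manual_model(
            {"antibody:h3k4me3": row(0.9), "antibody:h3k9ac": row(0.75)},
            tile_matrix=tiles,
        )
        doc = Document(id="q", tokens=(0,), labels={})
        ann = annotate_region_set(doc, model, threshold=0.1)
        assert ann.top("antibody") == "h3k4me3"
        assert ann.confidence("antibody") == pytest.approx(0.15)
        assert ann.confident("antibody")

        model2 = _manual_model(
            {"antibody:a": row(0.5), "antibody:b": row(0.45)}, tile_matrix=tiles
        )
        ann2 = annotate_region_set(doc, model2, threshold=0.1)
        assert ann2.confidence("antibody") == pytest.approx(0.05)
        assert not ann2.confident("antibody")

    def test_off_universe_query_is_an_error(self, toy_model):
        model, _, _ = toy_model
        with pytest.raises(ValueError, match="query off-universe"):
            annotate_region_set([Interval("chrZZ", 0, 500)], model)

    def test_training_document_recovers_its_label(self, toy_model):
        model, train_docs, _ = toy_model
        ann = annotate_region_set(train_docs[0], model)
        assert ann.top("antibody") == train_docs[0].labels["antibody"]
        ranked = ann.rankings["antibody"]
        assert set(ranked.ids) == {"a", "b"}


class TestScenario3:
    def test_identical_query_ranks_first_with_similarity_one(self, toy_model):
        model, train_docs, _ = toy_model
        db = embed_database(train_docs, model)
        # query has the same tokens as a database document but a new id,
        # so it is NOT excluded and must rank first at similarity 1
        twin = Document(id="twin", tokens=train_docs[0].tokens, labels={})
        res = retrieve_similar_region_sets(twin, model, db)
        assert res.entries[0][0] == train_docs[0].id
        assert res.entries[0][1] == pytest.approx(1.0)

    def test_query_excluded_from_its_own_database(self, toy_model):
        model, train_docs, _ = toy_model
        db = embed_database(train_docs, model)
        res = retrieve_similar_region_sets(train_docs[0], model, db)
        assert train_docs[0].id not in res.ids
        assert len(res.entries) == len(db) - 1

    def test_self_retrieval_before_exclusion(self, toy_model):
        """Every database document queried under a fresh id retrieves itself
        at rank 1 with similarity 1."""
        model, train_docs, _ = toy_model
        db = embed_database(train_docs, model)
        for doc in train_docs[:5]:
            probe = Document(id="probe", tokens=doc.tokens, labels={})
            res = retrieve_similar_region_sets(probe, model, db)
            assert res.entries[0][0] == doc.id
            assert res.entries[0][1] == pytest.approx(1.0)

    def test_ranking_invariant_to_query_rescaling(self, toy_model):
        model, train_docs, _ = toy_model
        db = embed_database(train_docs, model)
        res1 = retrieve_similar_region_sets(train_docs[3], model, db)
        scaled = {k: v * 7.5 for k, v in db.items()}
        res2 = retrieve_similar_region_sets(train_docs[3], model, scaled)
        assert res1.ids == res2.ids

    def test_similarities_bounded(self, toy_model):
        model, train_docs, _ = toy_model
        db = embed_database(train_docs, model)
        res = retrieve_similar_region_sets(train_docs[0], model, db)
        assert all(-1 - 1e-12 <= s <= 1 + 1e-12 for s in res.similarities)


def brute_force_rank(query_vec, db, model=None):
    """Naive all-pairs cosine scan: the independent ranking oracle."""
    from regionspace.model import cosine_similarity

    sims = [(doc_id, cosine_similarity(query_vec, v)) for doc_id, v in db.items()]
    return [doc_id for doc_id, s in sorted(sims, key=lambda e: (-e[1], e[0]))]


def test_rankings_match_bruteforce_scan_small():
    rng = np.random.default_rng(12)
    model = _manual_model({"antibody:x": rng.normal(size=3)})
    db = {f"doc{i:03d}": rng.normal(size=3) for i in range(200)}
    res = retrieve_region_sets_by_label("x", db, model)
    assert res.ids == brute_force_rank(model.dictionary.row("antibody:x"), db)
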