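"""The three retrieval scenarios over a trained co-embedding model.

Scenario 1: a metadata label is the query; the database region sets are
ranked by cosine similarity to the label's embedding row.
Scenario 2: a region set is the query; every label of each type is ranked by
similarity to the query embedding, annotating the region set.
Scenario 3: a region set is the query; database region sets are ranked by
similarity, retrieving its nearest neighbours in embedding space.

All rankings are deterministic: similarity descending, ties broken by
ascending entity id.
"""

from __future__ import annotations

import difflib
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import TrainedModel, cosine_similarity
from .universe import Document, Interval, normalize_label, tokenize_region_set

log = logging.getLogger(__name__)

__all__ = [
    "RankedResult",
    "AnnotationResult",
    "embed_database",
    "retrieve_region_sets_by_label",
    "annotate_region_set",
    "retrieve_similar_region_sets",
]


@dataclass(frozen=True)
class RankedResult:
    """Ordered (entity id, cosine similarity) list for one query."""

    query_id: str
    entries: tuple[tuple[str, float], ...]

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def similarities(self) -> list[float]:
        return [e[1] for e in self.entries]


@dataclass(frozen=True)
class AnnotationResult:
    """Per-label-type ranked annotations for one query region set.

    ``confidence`` is the similarity gap between the top two labels of a
    type; the prediction is flagged confident when the gap strictly exceeds
    the threshold.  A type with a single label has an infinite gap.
    """

    query_id: str
    rankings: Mapping[str, RankedResult]
    threshold: float = 0.1

    def top(self, label_type: str) -> str:
        return self.rankings[normalize_label(label_type)].entries[0][0]

    def confidence(self, label_type: str) -> float:
        entries = self.rankings[normalize_label(label_type)].entries
        if len(entries) < 2:
            return math.inf
        return entries[0][1] - entries[1][1]

    def confident(self, label_type: str) -> bool:
        return self.confidence(label_type) > self.threshold


def _rank(ids: Sequence[str], sims: np.ndarray) -> list[tuple[str, float]]:
    """Sort by similarity descending, then entity id ascending."""
    ids_arr = np.asarray(ids, dtype=object)
    order = sorted(range(len(ids)), key=lambda i: (-sims[i], ids_arr[i]))
    return [(str(ids_arr[i]), float(sims[i])) for i in order]


def _cosine_to_all(query: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    nq = np.linalg.norm(query)
    nv = np.linalg.norm(vectors, axis=1)
    if nq == 0.0 or np.any(nv == 0.0):
        raise ValueError("degenerate embedding: zero vector has no direction")
    return vectors @ query / (nv * nq)


def embed_database(
    documents: Sequence[Document], model: TrainedModel
) -> dict[str, np.ndarray]:
    """Embed a document database, keyed by document id.

    Documents whose tokens are all out of the model vocabulary are excluded
    with a warning rather than aborting the whole database.
    """
    if not documents:
        raise ValueError("empty database")
    out: dict[str, np.ndarray] = {}
    for doc in documents:
        try:
            out[doc.id] = model.embed_document(doc)
        except ValueError:
            log.warning("excluding document %s: no in-vocabulary tokens", doc.id)
    if not out:
        raise ValueError("empty database: no document had in-vocabulary tokens")
    return out


def retrieve_region_sets_by_label(
    query_label: str,
    db_vectors: Mapping[str, np.ndarray],
    model: TrainedModel,
    r: int | None = None,
) -> RankedResult:
    """Scenario 1: rank database region sets against a metadata label.

    ``query_label`` may be namespaced (``antibody:h3k4me3``) or bare
    (``h3k4me3``); a bare value is resolved against every label type and must
    be unambiguous.  ``r`` clamps the result length (default: whole database).
    """
    q = normalize_label(query_label)
    vocab_labels = model.dictionary.vocab[model.n_tiles :]
    if ":" in q and q in model.dictionary:
        feature = q
    else:
        matches = [name for name in vocab_labels if name.split(":", 1)[1] == q]
        if len(matches) > 1:
            raise ValueError(
                f"ambiguous label {query_label!r}: matches {', '.join(matches)}"
            )
        if not matches:
            near = difflib.get_close_matches(
                q, [n.split(":", 1)[1] for n in vocab_labels], n=5, cutoff=0.0
            )
            raise KeyError(
                f"unknown label {query_label!r}; nearest known labels: {', '.join(near)}"
            )
        feature = matches[0]
    qvec = model.dictionary.row(feature)
    ids = list(db_vectors)
    sims = _cosine_to_all(qvec, np.stack([db_vectors[i] for i in ids]))
    ranked = _rank(ids, sims)
    if r is not None:
        ranked = ranked[: max(r, 0)]
    return RankedResult(query_id=feature, entries=tuple(ranked))


def _as_document(
    query: Document | Iterable[Interval], model: TrainedModel, query_id: str = "query"
) -> Document:
    if isinstance(query, Document):
        return query
    try:
        return tokenize_region_set(list(query), model.universe, id=query_id)
    except ValueError as exc:
        raise ValueError(f"query off-universe: {exc}") from exc


def annotate_region_set(
    query: Document | Iterable[Interval],
    model: TrainedModel,
    threshold: float = 0.1,
) -> AnnotationResult:
    """Scenario 2: propose labels for a region set with missing metadata.

    For every label type known to the model, all labels of that type are
    ranked by cosine similarity to the query embedding; the top label is the
    proposed annotation and the gap to the runner-up is its confidence.
    """
    doc = _as_document(query, model)
    try:
        qvec = model.embed_document(doc)
    except ValueError as exc:
        raise ValueError(f"query off-universe: {exc}") from exc
    rankings: dict[str, RankedResult] = {}
    for ltype in model.label_types:
        values = model.label_values(ltype)
        vecs = np.stack([model.label_vector(ltype, v) for v in values])
        sims = _cosine_to_all(qvec, vecs)
        rankings[ltype] = RankedResult(
            query_id=doc.id, entries=tuple(_rank(values, sims))
        )
    return AnnotationResult(query_id=doc.id, rankings=rankings, threshold=threshold)


def retrieve_similar_region_sets(
    query: Document | Iterable[Interval],
    model: TrainedModel,
    db_vectors: Mapping[str, np.ndarray],
    r: int | None = None,
) -> RankedResult:
    """Scenario 3: rank database region sets against a query region set.

    If the query document's id is present in the database it is excluded
    from the results (by id only — duplicate content under another id is
    deliberately kept, which supports duplicate discovery).
    """
    doc = _as_document(query, model)
    try:
        qvec = model.embed_document(doc)
    except ValueError as exc:
        raise ValueError(f"query off-universe: {exc}") from exc
    ids = [i for i in db_vectors if i != doc.id]
    if not ids:
        raise ValueError("empty database after excluding the query itself")
    sims = _cosine_to_all(qvec, np.stack([db_vectors[i] for i in ids]))
    ranked = _rank(ids, sims)
    if r is not None:
        ranked = ranked[: max(r, 0)]
    return RankedResult(query_id=doc.id, entries=tuple(ranked))
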