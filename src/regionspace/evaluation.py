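"""Retrieval and annotation metrics, and the per-scenario evaluation report.

Implements the standard information-retrieval measures used to score the
three scenarios — r-precision, reciprocal rank / MRR, micro-averaged F1 and
the confusion matrix — plus the token-set Jaccard similarity that serves as
the overlap-based baseline for the embedding similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1

from .model import TrainedModel, cosine_similarity
from .retrieval import annotate_region_set, embed_database, retrieve_region_sets_by_label
from .universe import Document, label_feature

log = logging.getLogger(__name__)

__all__ = [
    "QueryOutcome",
    "ConfusionMatrix",
    "r_precision",
    "reciprocal_rank",
    "mean_reciprocal_rank",
    "micro_f1",
    "confusion_matrix",
    "jaccard_similarity",
    "evaluate_scenarios",
    "write_report",
]


@dataclass(frozen=True)
class QueryOutcome:
    """A ranked list with per-rank relevance flags for one query."""

    query_id: str
    ranked_ids: tuple[str, ...]
    relevant: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.ranked_ids) != len(self.relevant):
            raise ValueError("relevance flags must align with the ranked list")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts[i][j] = number of queries with true class i predicted as j."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


def r_precision(outcome: QueryOutcome, r: int) -> float:
    """Fraction of the top r retrieved items that are relevant."""
    if r <= 0:
        raise ValueError("r must be positive")
    if len(outcome.ranked_ids) < r:
        raise ValueError(
            f"ranked list of length {len(outcome.ranked_ids)} shorter than r={r}"
        )
    return sum(outcome.relevant[:r]) / r


def reciprocal_rank(outcome: QueryOutcome) -> float:
    """1 / (1-based rank of the first relevant item); 0 if none is relevant."""
    for i, rel in enumerate(outcome.relevant):
        if rel:
            return 1.0 / (i + 1)
    log.debug("query %s: no relevant item retrieved, RR=0", outcome.query_id)
    return 0.0


def mean_reciprocal_rank(outcomes: Sequence[QueryOutcome]) -> float:
    if not outcomes:
        raise ValueError("MRR of an empty query set is undefined")
    return float(np.mean([reciprocal_rank(o) for o in outcomes]))


def micro_f1(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> float:
    """F1 from TP/FP/FN summed over classes (equals accuracy when each query
    has exactly one true and one predicted label)."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    classes = sorted(set(true_labels) | set(predicted_labels))
    return float(
        _sk_f1(true_labels, predicted_labels, labels=classes, average="micro")
    )


def confusion_matrix(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    classes = sorted(set(true_labels) | set(predicted_labels))
    counts = _sk_confusion(true_labels, predicted_labels, labels=classes)
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def jaccard_similarity(doc_a: Document, doc_b: Document) -> float:
    """Intersection-over-union of two documents' universe token sets."""
    a, b = set(doc_a.tokens), set(doc_b.tokens)
    if not a or not b:
        raise ValueError("Jaccard similarity of an empty token set is undefined")
    return len(a & b) / len(a | b)


def evaluate_scenarios(
    model: TrainedModel,
    test_documents: Sequence[Document],
    database_documents: Sequence[Document] | None = None,
    threshold: float = 0.1,
) -> dict:
    """Score all three scenarios on a labelled test set.

    Scenario 1 queries every label of the model's label types against the
    test documents and reports per-label r-precision with r equal to the
    number of test documents truly bearing that label.  Scenario 2 annotates
    each test document and reports RR/MRR, top-1 accuracy, micro-F1 and a
    confusion matrix per label type.  Scenario 3 (when ``database_documents``
    is given, typically the training set) ranks the database against each
    test query and reports the mean embedding similarity grouped by
    (query label, database label) together with the Spearman correlation
    between embedding similarity and token-set Jaccard over all pairs.
    """
    if not test_documents:
        raise ValueError("empty test set")
    report: dict = {}
    test_vectors = embed_database(test_documents, model)
    by_id = {d.id: d for d in test_documents}

    # Scenario 1 — label -> region sets
    rows = []
    for ltype in model.label_types:
        for value in model.label_values(ltype):
            relevant_ids = {
                d.id for d in test_documents if d.labels.get(ltype) == value
            }
            if not relevant_ids:
                continue
            res = retrieve_region_sets_by_label(
                label_feature(ltype, value), test_vectors, model
            )
            outcome = QueryOutcome(
                query_id=res.query_id,
                ranked_ids=tuple(res.ids),
                relevant=tuple(i in relevant_ids for i in res.ids),
            )
            rows.append(
                {
                    "label_type": ltype,
                    "label": value,
                    "r": len(relevant_ids),
                    "r_precision": r_precision(outcome, len(relevant_ids)),
                }
            )
    s1 = pd.DataFrame(rows)
    report["scenario1"] = s1
    report["scenario1_mean"] = (
        s1.groupby("label_type")["r_precision"].mean().rename("mean_r_precision")
    ).reset_index()

    # Scenario 2 — region set -> labels
    rows = []
    for doc in test_documents:
        ann = annotate_region_set(doc, model, threshold=threshold)
        for ltype in model.label_types:
            true = doc.labels.get(ltype)
            if true is None:
                continue
            ranked = ann.rankings[ltype]
            outcome = QueryOutcome(
                query_id=doc.id,
                ranked_ids=tuple(ranked.ids),
                relevant=tuple(v == true for v in ranked.ids),
            )
            rows.append(
                {
                    "query_id": doc.id,
                    "label_type": ltype,
                    "true_label": true,
                    "predicted_label": ann.top(ltype),
                    "rr": reciprocal_rank(outcome),
                    "confidence": ann.confidence(ltype),
                    "confident": ann.confident(ltype),
                }
            )
    s2 = pd.DataFrame(rows)
    report["scenario2"] = s2
    summary, confusions = [], {}
    for ltype, grp in s2.groupby("label_type"):
        true = grp["true_label"].tolist()
        pred = grp["predicted_label"].tolist()
        confusions[ltype] = confusion_matrix(true, pred)
        summary.append(
            {
                "label_type": ltype,
                "n_queries": len(grp),
                "mrr": float(grp["rr"].mean()),
                "top1_accuracy": float(np.mean([t == p for t, p in zip(true, pred)])),
                "micro_f1": micro_f1(true, pred),
            }
        )
    report["scenario2_summary"] = pd.DataFrame(summary)
    report["scenario2_confusion"] = confusions

    # Scenario 3 — region set -> region sets
    if database_documents:
        db_vectors = embed_database(database_documents, model)
        db_by_id = {d.id: d for d in database_documents}
        pair_rows = []
        for doc in test_documents:
            qvec = test_vectors.get(doc.id)
            if qvec is None:
                continue
            for db_id, dvec in db_vectors.items():
                if db_id == doc.id:
                    continue
                pair_rows.append(
                    {
                        "query_id": doc.id,
                        "db_id": db_id,
                        "similarity": cosine_similarity(qvec, dvec),
                        "jaccard": jaccard_similarity(doc, db_by_id[db_id]),
                    }
                )
        s3 = pd.DataFrame(pair_rows)
        report["scenario3"] = s3
        rho = spearmanr(s3["jaccard"], s3["similarity"]).statistic
        report["scenario3_jaccard_spearman"] = float(rho)
        heats = {}
        for ltype in model.label_types:
            tmp = s3.assign(
                query_label=s3["query_id"].map(lambda i: by_id[i].labels.get(ltype)),
                db_label=s3["db_id"].map(lambda i: db_by_id[i].labels.get(ltype)),
            ).dropna(subset=["query_label", "db_label"])
            heats[ltype] = tmp.pivot_table(
                index="query_label", columns="db_label", values="similarity", aggfunc="mean"
            )
        report["scenario3_heat"] = heats
    return report


def write_report(report: Mapping, outdir) -> None:
    """Write the evaluation report as TSV files plus a plain-text summary."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("scenario1", "scenario1_mean", "scenario2", "scenario2_summary", "scenario3"):
        if key in report and isinstance(report[key], pd.DataFrame):
            report[key].to_csv(outdir / f"{key}.tsv", sep="\t", index=False, float_format="%.6g")
    for ltype, cm in report.get("scenario2_confusion", {}).items():
        cm.to_frame().to_csv(outdir / f"confusion_{ltype}.tsv", sep="\t")
    for ltype, heat in report.get("scenario3_heat", {}).items():
        heat.to_csv(outdir / f"scenario3_heat_{ltype}.tsv", sep="\t", float_format="%.6g")
    lines = ["evaluation summary", "=================="]
    if "scenario1_mean" in report:
        for _, row in report["scenario1_mean"].iterrows():
            lines.append(
                f"scenario 1 [{row['label_type']}]: mean r-precision {row['mean_r_precision']:.6g}"
            )
    if "scenario2_summary" in report:
        for _, row in report["scenario2_summary"].iterrows():
            lines.append(
                f"scenario 2 [{row['label_type']}]: MRR {row['mrr']:.6g}, "
                f"top-1 accuracy {row['top1_accuracy']:.6g}, micro-F1 {row['micro_f1']:.6g}"
            )
    if "scenario3_jaccard_spearman" in report:
        lines.append(
            "scenario 3: Spearman(jaccard, embedding similarity) "
            f"{report['scenario3_jaccard_spearman']:.6g}"
        )
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
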