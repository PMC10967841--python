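"""Readers and writers for the plain-text formats the toolchain exchanges.

Formats: BED3 region sets, two-column chrom.sizes tables, universe files
(BED3 of tiles with a ``# tile_size=`` sidecar line), document stores (one
line per tokenized region set, labels appended at the end of the token
list), and model files (StarSpace-style TSV of feature name + embedding
values, with a key:value sidecar recording the configuration).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model import EmbeddingDictionary, TrainConfig, TrainedModel
from .universe import ChromSizes, Document, Interval, Universe, build_universe

__all__ = [
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "write_universe",
    "read_universe",
    "write_documents",
    "read_documents",
    "write_model",
    "read_model",
]

_BED_SKIP = ("track", "browser", "#")


def read_chrom_sizes(path) -> ChromSizes:
    """Read a two-column (name, length) chrom.sizes table."""
    entries: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        name, length = line.split("\t")[:2]
        if name in entries:
            raise ValueError(f"duplicate chromosome {name!r} in {path}")
        entries[name] = int(length)
    return ChromSizes(entries)


def read_bed(path) -> list[Interval]:
    """Read the first three columns of a BED file; header-ish lines skipped."""
    out: list[Interval] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(_BED_SKIP):
            continue
        fields = line.rstrip("\n").split("\t")
        out.append(Interval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_universe(universe: Universe, path) -> None:
    """BED3 of all tiles, preceded by a sidecar line with the tile size."""
    with open(path, "w") as fh:
        fh.write(f"# tile_size={universe.tile_size}\n")
        for tile in universe.tiles:
            fh.write(f"{tile.chrom}\t{tile.start}\t{tile.end}\n")


def read_universe(path) -> Universe:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# tile_size="):
        raise ValueError(f"{path} is not a universe file (missing tile_size sidecar)")
    tile_size = int(lines[0].split("=", 1)[1])
    lengths: dict[str, int] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        chrom, _start, end = line.split("\t")[:3]
        lengths[chrom] = max(lengths.get(chrom, 0), int(end))
    return build_universe(ChromSizes(lengths), tile_size)


def write_documents(documents: Sequence[Document], path) -> None:
    """One line per document: id, token ids, then namespaced labels.

    Layout: ``id<TAB>tok tok tok ...<TAB>type:label type:label`` — the labels
    appended at the end of the tokenized region set, mirroring the training
    input layout of StarSpace-style tools.
    """
    with open(path, "w") as fh:
        for doc in documents:
            toks = " ".join(str(t) for t in doc.tokens)
            labels = " ".join(doc.label_features())
            fh.write(f"{doc.id}\t{toks}\t{labels}\n")


def read_documents(path) -> list[Document]:
    docs: list[Document] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        doc_id, toks, labels = (line.split("\t") + ["", ""])[:3]
        tokens = tuple(int(t) for t in toks.split()) if toks.strip() else ()
        label_map = {}
        for feat in labels.split():
            ltype, value = feat.split(":", 1)
            label_map[ltype] = value
        docs.append(Document(id=doc_id, tokens=tokens, labels=label_map))
    return docs


def write_model(model: TrainedModel, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.tsv`` (feature name + full-precision embedding values
    per row) and ``<prefix>.meta`` (key: value sidecar).  Returns both paths."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    meta = prefix.with_suffix(".meta")
    with open(tsv, "w") as fh:
        for name, row in zip(model.dictionary.vocab, model.dictionary.matrix):
            values = "\t".join(repr(float(x)) for x in row)
            fh.write(f"{name}\t{values}\n")
    cfg = model.config
    chroms = ",".join(model.universe.chroms)
    lengths = ",".join(str(L) for L in model.universe.chrom_lengths)
    meta_lines = [
        f"d: {cfg.d}",
        f"k: {cfg.k}",
        f"lr: {cfg.lr}",
        f"epochs: {cfg.epochs}",
        f"patience: {cfg.patience}",
        f"seed: {cfg.seed}",
        f"aggregation: {cfg.aggregation}",
        f"label_types_used: {','.join(cfg.label_types_used)}",
        f"tile_size: {model.universe.tile_size}",
        f"chroms: {chroms}",
        f"chrom_lengths: {lengths}",
    ]
    meta.write_text("\n".join(meta_lines) + "\n")
    return tsv, meta


def read_model(prefix) -> TrainedModel:
    """Read a model written by :func:`write_model` (round-trip exact)."""
    prefix = Path(prefix)
    meta = dict(
        line.split(": ", 1)
        for line in prefix.with_suffix(".meta").read_text().splitlines()
        if line.strip()
    )
    vocab: list[str] = []
    rows: list[list[float]] = []
    for line in prefix.with_suffix(".tsv").read_text().splitlines():
        fields = line.split("\t")
        vocab.append(fields[0])
        rows.append([float(x) for x in fields[1:]])
    dictionary = EmbeddingDictionary(vocab, np.array(rows, dtype=float))
    config = TrainConfig(
        d=int(meta["d"]),
        k=int(meta["k"]),
        lr=float(meta["lr"]),
        epochs=int(meta["epochs"]),
        patience=int(meta["patience"]),
        seed=int(meta["seed"]),
        aggregation=meta["aggregation"],
        label_types_used=tuple(meta["label_types_used"].split(",")),
    )
    chroms = meta["chroms"].split(",")
    lengths = [int(x) for x in meta["chrom_lengths"].split(",")]
    universe = build_universe(
        ChromSizes(dict(zip(chroms, lengths))), int(meta["tile_size"])
    )
    return TrainedModel(dictionary=dictionary, universe=universe, config=config)
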