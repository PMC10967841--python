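"""Synthetic labelled ChIP-seq-like corpora for training and evaluation.

The generator encodes the statistical structure the embedding model assumes
of real ChIP-seq peak collections: each metadata label (an antibody target or
a cell type) owns a *signature* — a fixed set of universe tiles where its
experiments place peaks — and each region set is a mixture of tiles drawn
from its two labels' signatures plus uniform background noise.  Designated
"similar" label pairs share a controllable fraction of their signature tiles,
a minimal analogue of biologically confusable labels such as closely related
histone modifications.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .universe import ChromSizes, Document, Interval, Universe, build_universe

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticCorpusConfig",
    "SyntheticCorpus",
    "generate_signatures",
    "generate_document",
    "generate_corpus_documents",
    "generate_corpus",
    "DEFAULT_ANTIBODIES",
    "DEFAULT_CELL_TYPES",
]

# Eight activating histone-modification targets and ten cell lines commonly
# profiled by ChIP-seq; the first two antibodies are the designated
# "similar" pair by default (di-/tri-methylation of the same residue).
DEFAULT_ANTIBODIES = (
    "h3k4me2",
    "h3k4me3",
    "h3k4me1",
    "h3k9ac",
    "h3k27ac",
    "h3k9me1",
    "h3k79me2",
    "h4k20me1",
)
DEFAULT_CELL_TYPES = (
    "k562",
    "mcf-7",
    "a549",
    "gm12878",
    "hepg2",
    "hela",
    "huvec",
    "imr90",
    "vcap",
    "lncap",
)


@dataclass(frozen=True)
class SyntheticCorpusConfig:
    """Generative parameters for a labelled synthetic corpus.

    Defaults describe the reference condition used throughout the test
    suite: a 2 Mb single-chromosome assembly tiled at 1 kb (2000 tiles),
    8 antibody x 10 cell-type labels with 40-tile signatures, 50% signature
    sharing between the one designated similar antibody pair, 20% background
    noise, 120 token draws per document and 4 documents per label
    combination (320 documents).
    """

    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000}
    )
    tile_size: int = 1000
    antibody_labels: tuple[str, ...] = DEFAULT_ANTIBODIES
    cell_type_labels: tuple[str, ...] = DEFAULT_CELL_TYPES
    signature_size: int = 40
    signature_overlap: float = 0.5
    similar_pairs: tuple[tuple[str, str], ...] = (("h3k4me2", "h3k4me3"),)
    noise_frac: float = 0.2
    tokens_per_doc: int = 120
    docs_per_combo: int = 4
    interval_style: str = "full_tile"  # or "random_subinterval"
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0 <= self.signature_overlap < 1:
            raise ValueError("signature_overlap must be in [0, 1)")
        if not 0 <= self.noise_frac <= 1:
            raise ValueError("noise_frac must be in [0, 1]")
        if min(self.signature_size, self.tokens_per_doc, self.docs_per_combo) < 1:
            raise ValueError("counts must be >= 1")
        if self.interval_style not in ("full_tile", "random_subinterval"):
            raise ValueError(f"unknown interval_style {self.interval_style!r}")
        labels = self.antibody_labels + self.cell_type_labels
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels across label lists")
        for a, b in self.similar_pairs:
            if a not in labels or b not in labels:
                raise ValueError(f"similar pair ({a!r}, {b!r}) not among the labels")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.antibody_labels + self.cell_type_labels

    def build_universe(self) -> Universe:
        return build_universe(ChromSizes(dict(self.chrom_sizes)), self.tile_size)


@dataclass(frozen=True)
class SyntheticCorpus:
    """Paths and in-memory mirror of one generated corpus."""

    root: Path
    bed_dir: Path
    metadata_path: Path
    chrom_sizes_path: Path
    manifest_path: Path
    documents: tuple[Document, ...]
    signatures: Mapping[str, frozenset[int]]
    universe: Universe


def generate_signatures(
    config: SyntheticCorpusConfig, rng: np.random.Generator
) -> dict[str, frozenset[int]]:
    """Assign each label its signature tile set.

    Signatures are pairwise disjoint except for the designated similar
    pairs, which share ``floor(signature_overlap * signature_size)`` tiles.
    """
    universe = config.build_universe()
    n_shared = int(config.signature_overlap * config.signature_size)
    paired = {lab for pair in config.similar_pairs for lab in pair}
    n_needed = (
        config.signature_size * len(config.labels)
        - n_shared * len(config.similar_pairs)
    )
    if n_needed > universe.n_tiles:
        raise ValueError(
            f"signature capacity exceeded: need {n_needed} tiles, "
            f"universe has {universe.n_tiles}; enlarge the assembly or "
            "shrink signature_size"
        )
    pool = list(rng.choice(universe.n_tiles, size=n_needed, replace=False))
    signatures: dict[str, frozenset[int]] = {}

    def take(n: int) -> list[int]:
        out = pool[:n]
        del pool[:n]
        return [int(t) for t in out]

    for a, b in config.similar_pairs:
        shared = take(n_shared)
        signatures[a] = frozenset(shared + take(config.signature_size - n_shared))
        signatures[b] = frozenset(shared + take(config.signature_size - n_shared))
    for lab in config.labels:
        if lab not in paired:
            signatures[lab] = frozenset(take(config.signature_size))
    return signatures


def _sample_signature_tokens(
    signature: frozenset[int], n: int, rng: np.random.Generator
) -> list[int]:
    """Up to n tiles without replacement; capped at the signature size."""
    pool = sorted(signature)
    if n >= len(pool):
        if n > len(pool):
            log.debug("signature token request %d capped at pool size %d", n, len(pool))
        return pool
    return [pool[i] for i in rng.choice(len(pool), size=n, replace=False)]


def generate_document(
    antibody: str,
    cell_type: str,
    signatures: Mapping[str, frozenset[int]],
    config: SyntheticCorpusConfig,
    rng: np.random.Generator,
) -> tuple[list[Interval], dict[str, str]]:
    """Draw one region set for an (antibody, cell type) combination.

    ``round((1 - noise_frac) * tokens_per_doc)`` signature token draws are
    split 50/50 between the two labels' signatures and sampled without
    replacement (capped at each signature's size); the remaining draws are
    uniform background over the whole universe.  The resulting token set is
    realized as full-tile intervals or seeded random sub-intervals of at
    least 50 bp.
    """
    universe = config.build_universe()
    n_sig = round((1 - config.noise_frac) * config.tokens_per_doc)
    n_ab = n_sig // 2
    n_ct = n_sig - n_ab
    tokens: set[int] = set()
    tokens.update(_sample_signature_tokens(signatures[antibody], n_ab, rng))
    tokens.update(_sample_signature_tokens(signatures[cell_type], n_ct, rng))
    n_noise = config.tokens_per_doc - n_sig
    if n_noise > universe.n_tiles:
        raise ValueError(
            f"requested {n_noise} background tokens from a {universe.n_tiles}-tile universe"
        )
    if n_noise:
        tokens.update(
            int(t) for t in rng.choice(universe.n_tiles, size=n_noise, replace=False)
        )
    intervals = []
    for tok in sorted(tokens):
        tile = universe.tile(tok)
        if config.interval_style == "full_tile":
            intervals.append(tile)
        else:
            span = tile.end - tile.start
            min_len = min(50, span)
            start = tile.start + int(rng.integers(0, span - min_len + 1))
            length = int(rng.integers(min_len, tile.end - start + 1))
            intervals.append(Interval(tile.chrom, start, start + length))
    return intervals, {"antibody": antibody, "cell_type": cell_type}


def _interval_token(iv: Interval, universe: Universe) -> int:
    # both interval styles keep each interval inside its source tile
    return universe.offsets[universe._chrom_index[iv.chrom]] + iv.start // universe.tile_size


def _draw_corpus(config, rng, signatures):
    universe = config.build_universe()
    for ab in config.antibody_labels:
        for ct in config.cell_type_labels:
            for rep in range(config.docs_per_combo):
                intervals, labels = generate_document(ab, ct, signatures, config, rng)
                doc_id = f"{ab}_{ct}_{rep:02d}".replace("/", "-")
                tokens = tuple(_interval_token(iv, universe) for iv in intervals)
                yield doc_id, sorted(intervals), labels, tokens


def generate_corpus_documents(
    config: SyntheticCorpusConfig,
) -> tuple[list[Document], dict[str, frozenset[int]], Universe]:
    """In-memory corpus: documents, true signatures and the universe.

    Uses the same seeded draws as :func:`generate_corpus` but skips all file
    I/O, which keeps repeated training experiments cheap.
    """
    universe = config.build_universe()
    rng = np.random.default_rng(config.seed)
    signatures = generate_signatures(config, rng)
    documents = [
        Document(id=doc_id, tokens=tokens, labels=labels)
        for doc_id, _, labels, tokens in _draw_corpus(config, rng, signatures)
    ]
    return documents, signatures, universe


def generate_corpus(config: SyntheticCorpusConfig, outdir) -> SyntheticCorpus:
    """Write a full corpus to disk: BED files, metadata TSV, chrom.sizes and
    a manifest recording the generative truth (config plus signatures)."""
    outdir = Path(outdir)
    bed_dir = outdir / "beds"
    if bed_dir.exists() and any(bed_dir.iterdir()):
        raise FileExistsError(f"output path collision: {bed_dir} is not empty")
    bed_dir.mkdir(parents=True, exist_ok=True)

    universe = config.build_universe()
    rng = np.random.default_rng(config.seed)
    signatures = generate_signatures(config, rng)
    documents: list[Document] = []
    meta_rows = ["id\tantibody\tcell_type"]
    for doc_id, intervals, labels, tokens in _draw_corpus(config, rng, signatures):
        with open(bed_dir / f"{doc_id}.bed", "w") as fh:
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        documents.append(Document(id=doc_id, tokens=tokens, labels=labels))
        meta_rows.append(f"{doc_id}\t{labels['antibody']}\t{labels['cell_type']}")

    metadata_path = outdir / "metadata.tsv"
    metadata_path.write_text("\n".join(meta_rows) + "\n")
    chrom_sizes_path = outdir / "genome.chrom.sizes"
    chrom_sizes_path.write_text(
        "".join(f"{c}\t{L}\n" for c, L in config.chrom_sizes.items())
    )
    manifest_lines = [
        f"seed: {config.seed}",
        f"tile_size: {config.tile_size}",
        f"signature_size: {config.signature_size}",
        f"signature_overlap: {config.signature_overlap}",
        f"noise_frac: {config.noise_frac}",
        f"tokens_per_doc: {config.tokens_per_doc}",
        f"docs_per_combo: {config.docs_per_combo}",
        f"interval_style: {config.interval_style}",
    ]
    for lab in config.labels:
        tiles = " ".join(str(t) for t in sorted(signatures[lab]))
        manifest_lines.append(f"signature {lab}: {tiles}")
    manifest_path = outdir / "manifest.txt"
    manifest_path.write_text("\n".join(manifest_lines) + "\n")
    return SyntheticCorpus(
        root=outdir,
        bed_dir=bed_dir,
        metadata_path=metadata_path,
        chrom_sizes_path=chrom_sizes_path,
        manifest_path=manifest_path,
        documents=tuple(documents),
        signatures=signatures,
        universe=universe,
    )
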