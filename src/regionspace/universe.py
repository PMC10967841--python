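"""Tiling universes and bag-of-tile tokenization of genomic region sets.

A *universe* is a fixed vocabulary of non-overlapping genome tiles obtained by
cutting every chromosome into consecutive windows of ``tile_size`` bp (the last
window of each chromosome is truncated at the chromosome end).  A region set —
a collection of intervals such as the peaks of one ChIP-seq experiment — is
*tokenized* by mapping each interval to the universe tiles it overlaps, turning
the region set into a bag-of-tokens document that can be embedded like a text
document over a shared vocabulary.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Strand is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "ChromSizes",
    "Interval",
    "Universe",
    "Document",
    "build_universe",
    "tokenize_interval",
    "tokenize_region_set",
    "normalize_label",
    "label_feature",
]


def normalize_label(value: str) -> str:
    """Case-normalize a metadata label: lowercase and strip whitespace."""
    return value.strip().lower()


def label_feature(label_type: str, value: str) -> str:
    """Namespaced feature name for a label, e.g. ``antibody:h3k4me3``.

    Namespacing keeps label vocabularies of different types from colliding
    when a model is trained on several label types at once.
    """
    return f"{normalize_label(label_type)}:{normalize_label(value)}"


@dataclass(frozen=True)
class ChromSizes:
    """Chromosome name -> length (bp) table describing an assembly."""

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty assembly")
        for name, length in self.entries.items():
            if not isinstance(length, int) or length < 1:
                raise ValueError(
                    f"chromosome {name!r} has invalid length {length!r}; lengths must be >= 1"
                )

    def __getitem__(self, chrom: str) -> int:
        return self.entries[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    def __iter__(self):
        return iter(self.entries)

    def items(self):
        return self.entries.items()


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in interval {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval {self}")


@dataclass(frozen=True)
class Universe:
    """Ordered set of fixed-width genome tiles acting as a token vocabulary.

    Tiles are numbered densely from 0 in (chromosome order, start) order, so
    the token id doubles as the row index of the tile's embedding in a model
    dictionary trained on this universe.
    """

    tile_size: int
    chroms: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    # first token id of each chromosome, in `chroms` order
    offsets: tuple[int, ...] = field(repr=False)
    n_tiles: int = field(repr=False, default=0)

    @cached_property
    def _chrom_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.chroms)}

    def tiles_in(self, chrom: str) -> int:
        """Number of tiles on a chromosome."""
        i = self._chrom_index[chrom]
        L = self.chrom_lengths[i]
        return -(-L // self.tile_size)  # ceil division

    def tile(self, token_id: int) -> Interval:
        """Interval spanned by a token id."""
        if not 0 <= token_id < self.n_tiles:
            raise IndexError(f"token id {token_id} outside universe of {self.n_tiles} tiles")
        # locate chromosome by offset (few chroms; linear scan is fine)
        for i in range(len(self.chroms) - 1, -1, -1):
            if token_id >= self.offsets[i]:
                j = token_id - self.offsets[i]
                start = j * self.tile_size
                end = min(start + self.tile_size, self.chrom_lengths[i])
                return Interval(self.chroms[i], start, end)
        raise AssertionError("unreachable")

    @cached_property
    def tiles(self) -> list[Interval]:
        """All tiles in token-id order."""
        out: list[Interval] = []
        for chrom, L in zip(self.chroms, self.chrom_lengths):
            for s in range(0, L, self.tile_size):
                out.append(Interval(chrom, s, min(s + self.tile_size, L)))
        return out

    @cached_property
    def token_ids(self) -> dict[Interval, int]:
        """Tile -> token id mapping (inverse of :attr:`tiles`)."""
        return {tile: i for i, tile in enumerate(self.tiles)}

    def feature_name(self, token_id: int) -> str:
        t = self.tile(token_id)
        return f"{t.chrom}:{t.start}-{t.end}"


def build_universe(chrom_sizes: ChromSizes | Mapping[str, int], tile_size: int) -> Universe:
    """Tile an assembly into a universe of ``tile_size``-bp tokens.

    Each chromosome of length L yields ceil(L / tile_size) tiles; the final
    tile is truncated at the chromosome end.  Token ids are dense from 0 in
    (chromosome, start) order.
    """
    if not isinstance(chrom_sizes, ChromSizes):
        chrom_sizes = ChromSizes(dict(chrom_sizes))
    if tile_size < 1:
        raise ValueError(f"tile_size must be >= 1, got {tile_size}")
    chroms = tuple(chrom_sizes)
    lengths = tuple(chrom_sizes[c] for c in chroms)
    offsets = []
    total = 0
    for L in lengths:
        offsets.append(total)
        total += -(-L // tile_size)
    return Universe(
        tile_size=tile_size,
        chroms=chroms,
        chrom_lengths=lengths,
        offsets=tuple(offsets),
        n_tiles=total,
    )


def tokenize_interval(
    iv: Interval, universe: Universe, overlap_mode: str = "all"
) -> list[int]:
    """Token ids of the universe tiles overlapped by one interval.

    ``overlap_mode="all"`` (default) returns every tile whose half-open span
    intersects the interval, in genomic order.  ``"max_overlap"`` returns a
    single token: the tile with the largest bp overlap, ties broken leftmost.
    Intervals on chromosomes absent from the universe yield an empty list.
    """
    idx = universe._chrom_index.get(iv.chrom)
    if idx is None:
        log.debug("interval %s on chromosome absent from universe", iv)
        return []
    L = universe.chrom_lengths[idx]
    if iv.start >= L:
        return []
    w = universe.tile_size
    n = -(-L // w)
    first = iv.start // w
    last = min((iv.end - 1) // w, n - 1)
    off = universe.offsets[idx]
    if overlap_mode == "all":
        return list(range(off + first, off + last + 1))
    if overlap_mode == "max_overlap":
        best_j, best_bp = first, -1
        for j in range(first, last + 1):
            tile_start, tile_end = j * w, min((j + 1) * w, L)
            bp = min(iv.end, tile_end) - max(iv.start, tile_start)
            if bp > best_bp:  # strict: ties keep the leftmost tile
                best_j, best_bp = j, bp
        return [off + best_j]
    raise ValueError(f"unknown overlap_mode {overlap_mode!r}")


@dataclass(frozen=True)
class Document:
    """A tokenized region set: a bag of tile tokens plus typed labels.

    Tokens are stored as a sorted, deduplicated tuple — the entity embedding
    is a sum/mean over token rows, so order and multiplicity are immaterial.
    Labels map a label type (e.g. ``"antibody"``) to a case-normalized value.
    """

    id: str
    tokens: tuple[int, ...]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        toks = tuple(sorted(set(self.tokens)))
        object.__setattr__(self, "tokens", toks)
        object.__setattr__(
            self,
            "labels",
            {normalize_label(t): normalize_label(v) for t, v in self.labels.items()},
        )

    def label_features(self, label_types: Sequence[str] | None = None) -> list[str]:
        """Namespaced label features, optionally restricted to some types."""
        types = self.labels.keys() if label_types is None else label_types
        return [
            label_feature(t, self.labels[t]) for t in types if t in self.labels
        ]


def tokenize_region_set(
    intervals: Iterable[Interval],
    universe: Universe,
    id: str,
    labels: Mapping[str, str] | None = None,
    overlap_mode: str = "all",
) -> Document:
    """Tokenize a region set into a :class:`Document`.

    Raises ``ValueError("empty document ...")`` if no interval maps to any
    universe tile — the signal that the input is off-assembly.
    """
    tokens: set[int] = set()
    n_iv = 0
    for iv in intervals:
        n_iv += 1
        tokens.update(tokenize_interval(iv, universe, overlap_mode=overlap_mode))
    if n_iv == 0:
        raise ValueError(f"empty document: region set {id!r} has no intervals")
    if not tokens:
        raise ValueError(
            f"empty document: no interval of region set {id!r} overlaps the universe"
        )
    return Document(id=id, tokens=tuple(tokens), labels=dict(labels or {}))
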