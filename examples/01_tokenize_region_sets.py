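"""Tile a genome into a token universe and tokenize a region set.

A region set (here three peaks on a toy 10 kb chromosome) becomes a bag of
tile tokens: each peak is mapped to every 1 kb universe tile it overlaps.
The token ids are what the embedding model consumes.
"""

from regionspace import Interval, build_universe, tokenize_region_set

universe = build_universe({"chr1": 10_000}, tile_size=1000)
print(f"universe: {universe.n_tiles} tiles of {universe.tile_size} bp")

peaks = [
    Interval("chr1", 150, 420),     # inside tile 0
    Interval("chr1", 1800, 2300),   # spans tiles 1 and 2
    Interval("chr1", 7000, 7100),   # tile 7
]
doc = tokenize_region_set(peaks, universe, id="example_peaks",
                          labels={"antibody": "H3K4me3"})
print(f"document {doc.id!r}: tokens {doc.tokens}, labels {doc.labels}")
for tok in doc.tokens:
    t = universe.tile(tok)
    print(f"  token {tok} -> {t.chrom}:{t.start}-{t.end}")
# Each token is a 1 kb genome tile hit by at least one peak; the bag of
# tokens (not the raw coordinates) is the model's view of the region set.
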