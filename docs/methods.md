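# Methods

## Model

`regionspace` learns a single embedding dictionary `D ∈ R^{D×d}` whose rows
are the vectors of all features: every tile of a fixed-width genome
tiling (the token universe) and every metadata label, namespaced by type
(`antibody:h3k4me3`, `cell_type:k562`) so that label vocabularies of
different types cannot collide in a combined model. An entity — a
region-set document (bag of tile features) or a label (single feature) —
is embedded by pooling its rows. The training objective is a softmax
negative-log-likelihood over cosine similarities: for a document `a` with
associated label `b⁺` and sampled negatives `b₁⁻..b_k⁻`,

    ℓ = −log( exp(s(a,b⁺)) / (exp(s(a,b⁺)) + Σᵢ exp(s(a,bᵢ⁻))) ),

computed with a log-sum-exp for stability. `ℓ ≥ 0`, equals `log(k+1)` when
all similarities coincide, and tends to 0 as the positive similarity
dominates — both limits are asserted in the tests, and the analytic
gradients of every touched row are checked against central finite
differences.

Optimization is plain per-pair stochastic gradient descent: each epoch
visits every (document, associated label) pair of every used label type in
a seeded shuffled order, samples `k` negatives uniformly without
replacement from the same label type's pool (capped at the pool size when
fewer are eligible), and applies the exact gradient of `ℓ` to the
document's token rows, the positive row and the negative rows. No
batching, momentum or adaptive step sizes are used; the simplicity keeps
the procedure fully reproducible from one seed.

### Tokenization

Coordinates are BED-convention 0-based half-open; strand is ignored. The
default overlap rule maps an interval to *every* tile its span intersects
(`overlap_mode="all"`); `"max_overlap"` instead picks the single tile with
the largest bp overlap, ties resolved leftmost. Both rules are closed-form
arithmetic on the fixed tile width, and the all-overlap implementation is
verified against a brute-force interval-tree scan. Documents are sets:
repeated tiles are deduplicated, and token order never affects the
embedding (a pooled bag is permutation-invariant).

### Corpus splitting and early stopping

A corpus of N documents is shuffled once (seeded) and split into a 15%
test set, then 10% of the remainder as validation, the rest as the
training core (floor rule at each step). After every epoch the mean pair
loss on the validation documents is computed with negatives drawn from a
fixed validation seed, so the curve is comparable across epochs; training
stops at the epoch budget or after `patience` epochs without improvement,
and the dictionary of the best validation epoch is returned.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `tile_size` | 1000 bp | universe tile width; the token granularity |
| `d` | 100 | embedding dimension |
| `k` | 10 | negatives per positive pair (capped at the eligible pool) |
| `lr` | 0.05 | SGD step size |
| `epochs` / `patience` | 50 / 5 | epoch budget and early-stopping patience |
| `aggregation` | mean | entity pooling; `sum` is the literal StarSpace formula |
| `threshold` | 0.1 | annotation confidence gap for a "confident" call |

The mean aggregation default keeps entity norms comparable across region
sets whose sizes span orders of magnitude; with cosine similarity the two
pooling modes give identical *directions* for a fixed bag, but their
gradient dynamics differ, so both are exposed. Dictionary rows are
initialized i.i.d. uniform on [−1/d, 1/d]: small, bounded, and
reproducible; nothing downstream depends on this particular choice.
Negatives are restricted to the label type of the positive so that a
combined-label model must separate labels within a type rather than merely
separating the types themselves.

## Retrieval semantics

All three scenarios rank by cosine similarity, descending, with ties
broken by ascending entity id — ranked lists are bit-reproducible, and the
ranking path is tested for exact agreement with a naive all-pairs scan.
Out-of-vocabulary tokens in external queries are dropped with a logged
count; a query with no in-vocabulary token is an error ("query
off-universe"), not an empty result. Scenario-3 self-exclusion is by
document id only, so an exact duplicate under a different id *is*
returned, which supports duplicate discovery. Label queries are matched
after case normalization; unknown labels raise an error that suggests the
nearest vocabulary strings, and no fuzzy matching enters the ranking path.
The annotation confidence is the similarity gap between the top two labels
of a type, compared strictly (`gap > threshold`); a type with a single
label is trivially confident (infinite gap).

## Metrics

r-precision uses r = number of truly relevant database documents for the
query label unless overridden, and per-label values are macro-averaged
across terms. Reciprocal rank of a ranking with no relevant item is
defined as 0 (logged; it cannot occur when the true label is in the
vocabulary). Micro-F1 sums TP/FP/FN over classes — in single-label
multi-class prediction it equals accuracy, a property the tests check
exhaustively at small n and by simulation at n = 1000. Micro-F1 and
confusion-matrix counting delegate to scikit-learn; r-precision, RR/MRR
and token-set Jaccard are implemented directly.

## Synthetic corpus

The generator emulates the structure that makes metadata-aware retrieval
of ChIP-seq region sets learnable: each label owns a `signature_size`-tile
signature; a document for an (antibody, cell type) pair draws
`round((1−noise_frac)·tokens_per_doc)` signature tokens, split evenly
between the two labels' signatures and sampled without replacement (capped
at each signature's size), plus uniform background tokens; designated
similar label pairs share `floor(signature_overlap·signature_size)` tiles,
a minimal analogue of biologically confusable labels such as di- vs
tri-methylation of the same histone residue. Intervals are realized as
full tiles or as seeded random sub-intervals of ≥ 50 bp, and tokenizing
the emitted BED files recovers the drawn token sets exactly — a round-trip
the tests assert in both styles.

The reference condition used throughout the test suite is one 2 Mb
chromosome tiled at 1 kb (2000 tiles), 8 antibody × 10 cell-type labels
with 40-tile signatures, one antibody pair sharing half its signature, 20%
noise, 120 token draws per document and 4 documents per combination (320
documents), seed 7. These sizes train in about a second on one CPU while
leaving every label with held-out test documents.

What the generator does *not* model: realistic peak-length and GC
distributions, chromatin-domain autocorrelation along the genome,
label-frequency imbalance, read-level noise, or many-to-many
label similarity graphs. Passing the synthetic recovery suite therefore
shows that the implementation learns the co-location structure it is
designed to learn — not that real-corpus accuracy figures would be
reproduced.

A consequence of the reference sizes worth stating explicitly: 96
signature draws against two 40-tile signatures saturate both, so every
document contains its labels' complete signatures and differs from its
class-mates only in background noise. The classes are then separable with
a wide margin and the trained models annotate the held-out split
perfectly, leaving empty off-diagonals in the confusion matrix — there is
no residual confusion between the overlapping antibody pair to observe at
these settings. Confusion between similar labels appears once documents
subsample their signatures (e.g. smaller `tokens_per_doc` or larger
signatures).

## Numerical choices and degenerate inputs

Cosine similarity of a zero vector is an error ("degenerate embedding"),
never silently 0; a non-finite training loss aborts with a hint to lower
the learning rate. Model files store embeddings at full `repr` precision,
so write → read → write is byte-identical; report TSVs round to 6
significant digits. All randomness flows from `numpy.random.default_rng`
seeded per run, with independent seed streams for initialization,
training, and validation negatives spawned from the one user seed.

## Limitations

Only fixed-width tiling universes are supported (no learned or merged
universes). Training is single-threaded pure-Python/numpy SGD — adequate
for desk-scale corpora (hundreds to thousands of documents), not for
repository-scale collections. Free-text queries outside the trained label
vocabulary are not supported, and no approximate nearest-neighbour index
is built: retrieval is an exact scan.
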