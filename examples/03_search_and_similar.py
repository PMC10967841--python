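"""Label-to-region-set search and region-set-to-region-set retrieval.

Scenario 1: a metadata label (e.g. an antibody name) retrieves the database
region sets most similar to the label's embedding.  Scenario 3: a query
region set retrieves its nearest neighbours among the database region sets.
"""

from regionspace import (
    TrainConfig,
    embed_database,
    retrieve_region_sets_by_label,
    retrieve_similar_region_sets,
    split_corpus,
    train,
)
from regionspace.synthetic import SyntheticCorpusConfig, generate_corpus_documents

config = SyntheticCorpusConfig(docs_per_combo=2, seed=7)
documents, _, universe = generate_corpus_documents(config)
train_core, validation, test = split_corpus(documents, seed=7)
model = train(train_core, validation, universe,
              TrainConfig(seed=7, label_types_used=("antibody",)))

database = embed_database(train_core, model)

print("scenario 1 — search for label 'h3k9ac':")
hits = retrieve_region_sets_by_label("h3k9ac", database, model, r=5)
for rank, (doc_id, sim) in enumerate(hits.entries, 1):
    print(f"  rank {rank}: {doc_id:25s} similarity {sim:.3f}")

query = test[0]
print(f"\nscenario 3 — region sets similar to {query.id!r} "
      f"(labels {dict(query.labels)}):")
similar = retrieve_similar_region_sets(query, model, database, r=5)
for rank, (doc_id, sim) in enumerate(similar.entries, 1):
    print(f"  rank {rank}: {doc_id:25s} similarity {sim:.3f}")
# Top hits should carry the queried label (scenario 1) or share the query's
# labels (scenario 3): similarity in embedding space tracks shared signatures.
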