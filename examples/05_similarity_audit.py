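"""Sketch-based similarity auditing between training and test phages.

Estimates k-mer Jaccard similarity with a bottom-k MinHash sketch, records
each test phage's maximum similarity to the training set, and bins phages
into five equal-width similarity intervals - the protocol used to study how
train/test overlap inflates apparent accuracy.  Also shows the leakage
filter that removes training negatives whose phage nearly matches a test
phage.
"""

import numpy as np

from pbip import (
    InteractionRecord,
    concatenated_proteome,
    downscale_profile,
    generate_dataset,
    leakage_filter,
    similarity_audit,
    sketch_similarity,
)

data = generate_dataset(downscale_profile("unit", seed=0))
seqs = {p.id: concatenated_proteome(p) for p in data.phages}
ids = list(seqs)
train_ids, test_ids = ids[:4], ids[4:]
train_seqs = {i: seqs[i] for i in train_ids}
# make one test phage a near-duplicate of a training phage
test_seqs = {test_ids[0]: seqs[train_ids[0]], test_ids[1]: seqs[test_ids[1]]}

s = sketch_similarity(test_seqs[test_ids[0]], train_seqs[train_ids[0]], k=11)
print(f"duplicate pair similarity: {s:.2f}")

results = [(pid, 1, 1) for pid in test_seqs]  # (phage, true, predicted)
audit = similarity_audit(test_seqs, train_seqs, results, k=11)
print("max similarity per test phage:",
      {k: round(v, 2) for k, v in audit.max_similarity.items()})
print("bin counts over [0,1]:", audit.bin_counts)

negatives = [InteractionRecord(pid, "b0", label=0) for pid in train_ids]
kept, removed = leakage_filter(
    negatives, train_seqs, test_seqs, similarity_threshold=0.9, k=11
)
print(f"leakage filter at 0.9: kept {len(kept)}, removed {len(removed)} "
      f"({[r['phage_id'] for r in removed]})")

# The phage whose proteome also appears in the test set is exactly what the
# leakage filter exists to catch: its negatives would let the model memorize
# test organisms.
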