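"""Balancing a skewed training set by SMOTE in the embedding space.

Creates an imbalanced set of labeled pair embeddings (12 positives vs 60
negatives), equalizes the classes by interpolating between nearest positive
neighbors, and audits the recorded provenance of one synthetic sample.
"""

import numpy as np

from pbip import PairEmbedding, SmoteConfig, balance_with_smote

rng = np.random.default_rng(42)
pairs = [
    PairEmbedding(f"p{i}", f"b{i}", x_p=rng.standard_normal(8) + 2.0 * label,
                  x_b=rng.standard_normal(8), label=label)
    for i, label in enumerate([1] * 12 + [0] * 60)
]

balanced = balance_with_smote(pairs, SmoteConfig(k_neighbors=5, seed=0))
labels = [p.label for p in balanced]
print(f"before: {sum(p.label for p in pairs)} positives / "
      f"{sum(1 - p.label for p in pairs)} negatives")
print(f"after:  {labels.count(1)} positives / {labels.count(0)} negatives")

sample = next(p for p in balanced if p.synthetic)
parents = [p for p in pairs if p.label == 1]
a, b = parents[sample.parent_a].vector, parents[sample.parent_b].vector
residual = np.max(np.abs(sample.vector - (a + sample.alpha * (b - a))))
print(f"one synthetic sample: parents #{sample.parent_a} and #{sample.parent_b}, "
      f"alpha={sample.alpha:.3f}, collinearity residual {residual:.1e}")

# Every synthetic positive lies exactly on the segment between two real
# positives; negatives and the originals are never modified.
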