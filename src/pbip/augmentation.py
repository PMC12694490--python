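"""Embedding-space SMOTE for balancing positive phage-bacterium pairs.

Training matrices are heavily skewed toward negatives (most strains resist
most phages), so the minority positives are oversampled by linear
interpolation in the pair-embedding space:

    [x_p, x_b]' = [x_p, x_b] + alpha * ([x_p, x_b]_n - [x_p, x_b])

where [x_p, x_b]_n is one of the k nearest positive neighbors and
alpha ~ Uniform[0, 1].  Interpolation acts on the whole concatenated pair
vector.  Enough synthetic positives are added to equalize the class counts;
negatives and all original samples are left untouched.  Synthetic samples
record their parents and alpha so the interpolation can be audited.

This must only ever be applied to training splits; evaluation code holds test
sets out before augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .embedder import PairEmbedding


class SmoteError(ValueError):
    pass


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise SmoteError("k_neighbors must be >= 1")


def minority_neighbors(minority_vectors: np.ndarray, k: int) -> np.ndarray:
    """Indices of each minority vector's k nearest minority vectors.

    Euclidean distance, self excluded.  Shape (n, k).
    """
    X = np.asarray(minority_vectors, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise SmoteError(f"k={k} must be smaller than the minority count n={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    idx = nn.kneighbors(X, return_distance=False)
    out = np.empty((n, k), dtype=np.intp)
    for i in range(n):
        row = [j for j in idx[i] if j != i][:k]
        # all-duplicate inputs can return fewer non-self hits; pad arbitrarily
        while len(row) < k:
            row.append(next(j for j in range(n) if j != i))
        out[i] = row
    return out


def interpolate(x: np.ndarray, x_n: np.ndarray, alpha: float) -> np.ndarray:
    """Point on the segment from x to its neighbor x_n at fraction alpha."""
    if not 0.0 <= alpha <= 1.0:
        raise SmoteError(f"alpha={alpha} outside [0, 1]")
    x = np.asarray(x, dtype=float)
    x_n = np.asarray(x_n, dtype=float)
    if x.shape != x_n.shape:
        raise SmoteError(f"shape mismatch {x.shape} vs {x_n.shape}")
    return x + alpha * (x_n - x)


def balance_with_smote(
    pairs: list[PairEmbedding], config: SmoteConfig | None = None
) -> list[PairEmbedding]:
    """Equalize class counts by synthesizing positive pair embeddings.

    Originals are preserved unmodified (and first, in order); each synthetic
    sample is a convex combination of a random positive and one of its
    ``k_neighbors`` nearest positives, labeled 1 and flagged synthetic with
    provenance (parent indices into the positive subset, alpha).  If positives
    already match or exceed negatives the input is returned unchanged.
    """
    config = config or SmoteConfig()
    labels = [p.label for p in pairs]
    if any(y is None for y in labels):
        raise SmoteError("all pairs must be labeled before augmentation")
    pos_idx = [i for i, y in enumerate(labels) if y == 1]
    neg_idx = [i for i, y in enumerate(labels) if y == 0]
    if not pos_idx or not neg_idx:
        raise SmoteError("both classes must be present")
    n_needed = len(neg_idx) - len(pos_idx)
    if n_needed <= 0:
        return list(pairs)
    if len(pos_idx) <= config.k_neighbors:
        raise SmoteError(
            f"only {len(pos_idx)} positives but k_neighbors={config.k_neighbors}; "
            "use a smaller k"
        )
    pos_vectors = np.stack([pairs[i].vector for i in pos_idx])
    neighbors = minority_neighbors(pos_vectors, config.k_neighbors)
    rng = np.random.default_rng(config.seed)
    d_h = pairs[pos_idx[0]].d_h

    out = list(pairs)
    seeds = rng.integers(0, len(pos_idx), size=n_needed)
    picks = rng.integers(0, config.k_neighbors, size=n_needed)
    alphas = rng.uniform(0.0, 1.0, size=n_needed)
    for s, pick, alpha in zip(seeds, picks, alphas):
        nbr = neighbors[s, pick]
        vec = interpolate(pos_vectors[s], pos_vectors[nbr], float(alpha))
        parent = pairs[pos_idx[s]]
        out.append(
            PairEmbedding(
                phage_id=f"synthetic:{parent.phage_id}",
                bacterium_id=f"synthetic:{parent.bacterium_id}",
                x_p=vec[:d_h],
                x_b=vec[d_h:],
                label=1,
                synthetic=True,
                parent_a=int(s),
                parent_b=int(nbr),
                alpha=float(alpha),
            )
        )
    return out


def passthrough(pairs: list[PairEmbedding], config: SmoteConfig | None = None) -> list[PairEmbedding]:
    """No-op augmentation used by the no-SMOTE ablation variant."""
    return list(pairs)
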