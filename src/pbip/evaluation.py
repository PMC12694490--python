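"""Evaluation protocol: metrics, cross-validation, imbalance and similarity studies.

Eight metrics summarize a prediction run: accuracy, precision, sensitivity
(recall), specificity, F1, Matthews correlation coefficient, area under the
ROC curve and area under the precision-recall curve.  Degenerate ratios follow
the common conventions: precision = 0 when no positives are predicted, MCC = 0
when any denominator factor vanishes, F1 = 0 when precision + recall = 0.

Protocol pieces mirror the study design for strain-level interaction data:
stratified 10-fold cross-validation with augmentation applied inside each
training split only; nine imbalanced test sets at positive:negative ratios
1:2 .. 1:10; a MinHash k-mer Jaccard similarity audit binning test phages by
their maximum similarity to any training phage; and a leakage filter removing
training negatives whose phage closely matches a test phage.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold

from .augmentation import SmoteConfig, balance_with_smote
from .embedder import PairEmbedding
from .network import ModelConfig, TrainConfig, train_model
from .sequence_io import InteractionRecord


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts with scores >= threshold predicted positive."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise EvaluationError(f"length mismatch: {s.shape} vs {y.shape}")
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def scalar_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, sensitivity, specificity, F1 and MCC from counts."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise EvaluationError("empty confusion table")
    accuracy = (tp + tn) / counts.total
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    sensitivity = tp / (tp + fn) if tp + fn > 0 else 0.0
    specificity = tn / (fp + tn) if fp + tn > 0 else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity > 0
        else 0.0
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return {
        "accuracy": accuracy,
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
        "mcc": float(mcc),
    }


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus ROC curve points (fpr, tpr).

    Equals the probability that a random positive outscores a random negative,
    ties counted one half (the Mann-Whitney identity).
    """
    y = np.asarray(labels, dtype=int)
    if len(set(y.tolist())) < 2:
        raise EvaluationError("roc_auc needs both classes present")
    fpr, tpr, _ = skm.roc_curve(y, scores)
    return float(skm.roc_auc_score(y, scores)), fpr, tpr


def pr_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUPR (step-wise, non-interpolated) plus PR curve points (recall, precision)."""
    y = np.asarray(labels, dtype=int)
    if int(np.sum(y == 1)) == 0:
        raise EvaluationError("pr_auc needs at least one positive")
    precision, recall, _ = skm.precision_recall_curve(y, scores)
    return float(skm.average_precision_score(y, scores)), recall, precision


@dataclass
class MetricsReport:
    """The eight evaluation metrics plus ROC/PR curve points for one run."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    auc: float
    aupr: float
    roc_curve: tuple[np.ndarray, np.ndarray] | None = None
    pr_curve: tuple[np.ndarray, np.ndarray] | None = None

    def to_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in (
                "accuracy",
                "precision",
                "sensitivity",
                "specificity",
                "f1",
                "mcc",
                "auc",
                "aupr",
            )
        }


def evaluate_predictions(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    curves: bool = True,
) -> MetricsReport:
    counts = confusion(scores, labels, threshold)
    scalars = scalar_metrics(counts)
    auc, fpr, tpr = roc_auc(scores, labels)
    aupr, recall, precision = pr_auc(scores, labels)
    return MetricsReport(
        **scalars,
        auc=auc,
        aupr=aupr,
        roc_curve=(fpr, tpr) if curves else None,
        pr_curve=(recall, precision) if curves else None,
    )


# ---------------------------------------------------------------------------
# Cross-validation


def kfold_cv(
    pairs: Sequence[PairEmbedding],
    k: int = 10,
    seed: int = 0,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    use_smote: bool = True,
    smote_config: SmoteConfig | None = None,
) -> dict:
    """Stratified k-fold cross-validation of the full train/evaluate pipeline.

    Folds are disjoint and exhaustive; augmentation is applied inside each
    training split only (the held-out fold is never augmented).  Returns
    per-fold reports plus per-metric mean and standard deviation.
    """
    y = np.array([p.label for p in pairs], dtype=int)
    if len(pairs) < k:
        raise EvaluationError(f"need at least k={k} pairs")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_reports: list[MetricsReport] = []
    assignments = np.full(len(pairs), -1, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(pairs)), y)):
        if len(set(y[test_idx].tolist())) < 2 or len(set(y[train_idx].tolist())) < 2:
            raise EvaluationError(
                f"fold {fold} lacks a class; stratify or reduce k"
            )
        assignments[test_idx] = fold
        train_pairs = [pairs[i] for i in train_idx]
        if use_smote:
            train_pairs = balance_with_smote(
                train_pairs, smote_config or SmoteConfig(seed=seed + fold)
            )
        model, _ = train_model(train_pairs, model_config, train_config, seed=seed + fold)
        test_pairs = [pairs[i] for i in test_idx]
        scores = model.predict(test_pairs)
        fold_reports.append(
            evaluate_predictions(scores, y[test_idx], curves=False)
        )
    table = {m: [getattr(r, m) for r in fold_reports] for m in fold_reports[0].to_dict()}
    return {
        "folds": fold_reports,
        "assignments": assignments,
        "mean": {m: float(np.mean(v)) for m, v in table.items()},
        "sd": {m: float(np.std(v, ddof=1)) for m, v in table.items()},
    }


def imbalanced_test_sets(
    positives: Sequence,
    negative_pool: Sequence,
    ratios: Sequence[int] = tuple(range(2, 11)),
    seed: int = 0,
    allow_other_ratios: bool = False,
) -> dict[int, list]:
    """Nine test sets at positive:negative ratios 1:2 .. 1:10.

    Each set contains all positives plus ratio * len(positives) negatives
    sampled without replacement from the pool; reproducible for a fixed seed.
    """
    if not allow_other_ratios:
        bad = [r for r in ratios if not 2 <= r <= 10]
        if bad:
            raise EvaluationError(
                f"ratios {bad} outside the 1:2..1:10 protocol "
                "(set allow_other_ratios=True to override)"
            )
    n_pos = len(positives)
    for r in sorted(ratios):
        if r * n_pos > len(negative_pool):
            raise EvaluationError(
                f"ratio 1:{r} needs {r * n_pos} negatives, pool has {len(negative_pool)}"
            )
    rng = np.random.default_rng(seed)
    out: dict[int, list] = {}
    for r in ratios:
        chosen = rng.choice(len(negative_pool), size=r * n_pos, replace=False)
        out[r] = list(positives) + [negative_pool[i] for i in chosen]
    return out


# ---------------------------------------------------------------------------
# Sketch-based sequence similarity (MinHash stand-in for HLL sketching tools)


def _kmer_hashes(seq: str, k: int, salt: bytes) -> set[int]:
    return {
        int.from_bytes(
            hashlib.blake2b(seq[i : i + k].encode(), digest_size=8, key=salt).digest(),
            "big",
        )
        for i in range(len(seq) - k + 1)
    }


def sketch_similarity(
    seq_a: str, seq_b: str, k: int = 21, sketch_size: int = 1024, hash_seed: int = 0
) -> float:
    """Bottom-k MinHash estimate of the Jaccard similarity of two k-mer sets.

    Deterministic for a fixed hash seed and symmetric.  When either sequence
    has at most ``sketch_size`` distinct k-mers the estimate is the exact
    Jaccard index.
    """
    for name, s in (("seq_a", seq_a), ("seq_b", seq_b)):
        if len(s) < k:
            raise EvaluationError(f"{name} shorter than k={k}")
    salt = hash_seed.to_bytes(8, "big")
    ha = _kmer_hashes(seq_a.upper(), k, salt)
    hb = _kmer_hashes(seq_b.upper(), k, salt)
    sa = set(sorted(ha)[:sketch_size])
    sb = set(sorted(hb)[:sketch_size])
    union_bottom = set(sorted(sa | sb)[:sketch_size])
    inter = union_bottom & sa & sb
    if not union_bottom:
        return 0.0
    return len(inter) / len(union_bottom)


@dataclass
class SimilarityAudit:
    """Per-test-phage max similarity to training phages, binned, with accuracy."""

    max_similarity: dict[str, float]
    bin_edges: np.ndarray
    bin_counts: list[int]
    bin_pair_counts: list[int]
    bin_accuracy: list[float | None]


def similarity_audit(
    test_phage_seqs: Mapping[str, str],
    train_phage_seqs: Mapping[str, str],
    pair_results: Sequence[tuple[str, int, int]],
    bins: int = 5,
    k: int = 21,
    sketch_size: int = 1024,
    similarity_fn: Callable[[str, str], float] | None = None,
) -> SimilarityAudit:
    """Bin test phages by max similarity to the training set; report accuracy.

    ``pair_results`` holds (phage_id, true_label, predicted_label) per test
    pair.  Bins are ``bins`` equal-width intervals over [0, 1]; a bin with no
    pairs reports accuracy None.
    """
    sim = similarity_fn or (
        lambda a, b: sketch_similarity(a, b, k=k, sketch_size=sketch_size)
    )
    max_sim = {
        pid: max(sim(pseq, tseq) for tseq in train_phage_seqs.values())
        for pid, pseq in test_phage_seqs.items()
    }
    edges = np.linspace(0.0, 1.0, bins + 1)
    which = {
        pid: min(int(np.searchsorted(edges, s, side="right")) - 1, bins - 1)
        for pid, s in max_sim.items()
    }
    counts = [0] * bins
    for b in which.values():
        counts[b] += 1
    pair_counts = [0] * bins
    correct = [0] * bins
    for pid, y_true, y_pred in pair_results:
        if pid not in which:
            raise EvaluationError(f"result for unknown test phage {pid!r}")
        b = which[pid]
        pair_counts[b] += 1
        correct[b] += int(y_true == y_pred)
    accuracy = [
        (correct[b] / pair_counts[b]) if pair_counts[b] > 0 else None
        for b in range(bins)
    ]
    return SimilarityAudit(
        max_similarity=max_sim,
        bin_edges=edges,
        bin_counts=counts,
        bin_pair_counts=pair_counts,
        bin_accuracy=accuracy,
    )


def leakage_filter(
    training_negatives: Sequence[InteractionRecord],
    train_phage_seqs: Mapping[str, str],
    test_phage_seqs: Mapping[str, str],
    similarity_threshold: float = 0.9,
    k: int = 21,
    sketch_size: int = 1024,
    similarity_fn: Callable[[str, str], float] | None = None,
) -> tuple[list[InteractionRecord], list[dict]]:
    """Drop training negatives whose phage closely matches any test phage.

    A negative is removed when its phage's maximum similarity to the test
    phages is >= ``similarity_threshold``.  Returns (kept, removal log).
    """
    sim = similarity_fn or (
        lambda a, b: sketch_similarity(a, b, k=k, sketch_size=sketch_size)
    )
    max_sim: dict[str, float] = {}
    for pid in {r.phage_id for r in training_negatives}:
        if pid not in train_phage_seqs:
            raise EvaluationError(f"no sequence for training phage {pid!r}")
        max_sim[pid] = (
            max(sim(train_phage_seqs[pid], t) for t in test_phage_seqs.values())
            if test_phage_seqs
            else 0.0
        )
    kept: list[InteractionRecord] = []
    removed: list[dict] = []
    for rec in training_negatives:
        s = max_sim[rec.phage_id]
        if s >= similarity_threshold:
            removed.append(
                {
                    "phage_id": rec.phage_id,
                    "bacterium_id": rec.bacterium_id,
                    "max_similarity": s,
                }
            )
        else:
            kept.append(rec)
    return kept, removed
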