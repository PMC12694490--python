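"""Metrics vs brute-force oracles; CV, imbalance, similarity and leakage protocols."""

import numpy as np
import pytest

from conftest import make_pairs, tiny_model_config, tiny_train_config
from pbip.evaluation import (
    ConfusionCounts,
    EvaluationError,
    confusion,
    evaluate_predictions,
    imbalanced_test_sets,
    kfold_cv,
    leakage_filter,
    pr_auc,
    roc_auc,
    scalar_metrics,
    similarity_audit,
    sketch_similarity,
)
from pbip.sequence_io import InteractionRecord


def mann_whitney_auc(scores, labels):
    """O(n^2) pair-enumeration oracle: ties count one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def step_ap(scores, labels):
    """Per-threshold recomputation oracle for the step-wise PR area."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n_pos = y.sum()
    ap, tp, prev_recall = 0.0, 0, 0.0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:  # all samples at one threshold enter together
            j += 1
        tp += y[i:j].sum()
        precision = tp / j
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


class TestConfusion:
    def test_scores_equal_labels(self):
        c = confusion([1, 0, 1, 0], [1, 0, 1, 0])
        assert (c.fp, c.fn) == (0, 0) and (c.tp, c.tn) == (2, 2)

    def test_threshold_tie_counts_positive(self):
        c = confusion([0.5, 0.5], [1, 0])
        assert c.tp == 1 and c.fp == 1 and c.tn == 0

    def test_random_instance_matches_per_pair_loop(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 20)
        labels = rng.integers(0, 2, 20)
        c = confusion(scores, labels)
        tp = tn = fp = fn = 0
        for s, y in zip(scores, labels):
            pred = s >= 0.5
            if pred and y == 1:
                tp += 1
            elif pred and y == 0:
                fp += 1
            elif not pred and y == 1:
                fn += 1
            else:
                tn += 1
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        assert c.total == 20

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            confusion([0.5], [1, 0])


class TestScalarMetrics:
    def test_perfect_classifier(self):
        m = scalar_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_plug_in_arithmetic_example(self):
        m = scalar_metrics(ConfusionCounts(tp=45, fn=5, tn=35, fp=15))
        assert m["accuracy"] == pytest.approx(0.80)
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(0.70)
        assert m["precision"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(2 * 0.75 * 0.90 / (0.75 + 0.90))
        mcc = (45 * 35 - 15 * 5) / np.sqrt(60 * 50 * 50 * 40)
        assert m["mcc"] == pytest.approx(mcc)

    def test_all_negative_predictions_use_conventions(self):
        m = scalar_metrics(ConfusionCounts(tp=0, fp=0, tn=8, fn=2))
        assert m["precision"] == 0.0 and m["mcc"] == 0.0 and m["f1"] == 0.0

    def test_thousand_random_tables_match_formulas(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 40, 4)
            if tp + tn + fp + fn == 0:
                continue
            m = scalar_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            total = tp + tn + fp + fn
            assert m["accuracy"] == pytest.approx((tp + tn) / total, abs=1e-12)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            assert m["precision"] == pytest.approx(prec, abs=1e-12)
            assert m["sensitivity"] == pytest.approx(rec, abs=1e-12)
            assert m["specificity"] == pytest.approx(
                tn / (fp + tn) if fp + tn else 0.0, abs=1e-12
            )
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
            assert m["mcc"] == pytest.approx(mcc, abs=1e-12)
            # F1 is the harmonic mean of precision and recall when defined
            if prec + rec > 0:
                assert m["f1"] == pytest.approx(2 * prec * rec / (prec + rec), abs=1e-12)


class TestRocAuc:
    def test_perfect_and_anti_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])[0] == 1.0
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])[0] == 0.0

    def test_ties_counted_half_against_oracle(self):
        scores = [0.5, 0.5, 0.5, 0.7, 0.2, 0.7, 0.1, 0.9, 0.3, 0.5, 0.2, 0.8]
        labels = [1, 0, 1, 0, 1, 1, 0, 1, 0, 0, 1, 0]
        auc, _, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_random_instances_match_mann_whitney(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            auc, _, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        a1, _, _ = roc_auc(scores, labels)
        a2, _, _ = roc_auc(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([0.1, 0.9], [1, 1])


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])[0] == 1.0

    def test_constant_scores_give_prevalence(self):
        aupr, _, _ = pr_auc([0.5] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        assert aupr == pytest.approx(0.3)

    def test_small_instances_match_threshold_sweep_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            scores = rng.choice([0.2, 0.4, 0.6, 0.8], n)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                continue
            aupr, _, _ = pr_auc(scores, labels)
            assert aupr == pytest.approx(step_ap(scores, labels), abs=1e-12)

    def test_no_positive_rejected(self):
        with pytest.raises(EvaluationError):
            pr_auc([0.5, 0.6], [0, 0])


class TestReport:
    def test_report_fields_in_range(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 1, 40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        r = evaluate_predictions(scores, labels)
        for name, v in r.to_dict().items():
            if name == "mcc":
                assert -1 <= v <= 1
            else:
                assert 0 <= v <= 1
        assert r.roc_curve is not None and r.pr_curve is not None


class TestKfold:
    def run_cv(self, n_pos=30, n_neg=70, k=10, seed=0):
        pairs = make_pairs(n_pos, n_neg, d_h=12, seed=seed, separation=2.0)
        return pairs, kfold_cv(
            pairs,
            k=k,
            seed=seed,
            model_config=tiny_model_config(seed=seed),
            train_config=tiny_train_config(epochs=2),
            use_smote=True,
        )

    def test_folds_partition_the_data(self):
        pairs, result = self.run_cv()
        a = result["assignments"]
        assert len(a) == 100 and set(a.tolist()) == set(range(10))
        # disjoint + exhaustive: every pair has exactly one fold
        assert np.all(a >= 0)
        assert np.bincount(a).sum() == 100

    def test_hundred_pairs_ten_folds_of_ten(self):
        _, result = self.run_cv()
        assert np.bincount(result["assignments"]).tolist() == [10] * 10

    def test_same_seed_reproduces_assignments(self):
        _, r1 = self.run_cv(seed=3)
        _, r2 = self.run_cv(seed=3)
        assert np.array_equal(r1["assignments"], r2["assignments"])

    def test_stratified_fold_class_ratio_within_one_sample(self):
        pairs, result = self.run_cv()
        labels = np.array([p.label for p in pairs])
        for fold in range(10):
            fold_pos = labels[result["assignments"] == fold].sum()
            assert abs(fold_pos - 3) <= 1  # 30% of 10 per fold

    def test_mean_and_sd_reported_per_metric(self):
        _, result = self.run_cv()
        for key in ("accuracy", "mcc", "auc", "aupr"):
            assert key in result["mean"] and key in result["sd"]

    def test_too_few_pairs_rejected(self):
        pairs = make_pairs(2, 2, d_h=12)
        with pytest.raises(EvaluationError):
            kfold_cv(pairs, k=10)


class TestImbalancedSets:
    def test_published_test_set_arithmetic(self):
        positives = [("p", i) for i in range(191)]
        pool = [("n", i) for i in range(1910)]
        sets = imbalanced_test_sets(positives, pool, seed=0)
        assert len(sets) == 9 and sorted(sets) == list(range(2, 11))
        s2 = sets[2]
        assert len(s2) == 573  # 191 positives + 382 negatives
        assert sum(1 for x in s2 if x[0] == "n") == 382

    def test_exact_negative_counts_per_ratio(self):
        positives = list(range(20))
        pool = [100 + i for i in range(200)]
        sets = imbalanced_test_sets(positives, pool, seed=1)
        for r, s in sets.items():
            negatives = [x for x in s if x >= 100]
            assert len(negatives) == r * 20
            assert len(set(negatives)) == len(negatives)  # without replacement

    def test_reproducible_per_seed(self):
        positives = list(range(10))
        pool = list(range(100, 250))
        a = imbalanced_test_sets(positives, pool, seed=5)
        b = imbalanced_test_sets(positives, pool, seed=5)
        assert a == b

    def test_insufficient_pool_names_first_infeasible_ratio(self):
        with pytest.raises(EvaluationError, match="1:8"):
            imbalanced_test_sets(list(range(10)), list(range(75)), seed=0)

    def test_out_of_protocol_ratio_needs_override(self):
        positives = list(range(5))
        pool = list(range(100))
        with pytest.raises(EvaluationError):
            imbalanced_test_sets(positives, pool, ratios=[1], seed=0)
        sets = imbalanced_test_sets(
            positives, pool, ratios=[1], seed=0, allow_other_ratios=True
        )
        assert len(sets[1]) == 10


def random_protein(rng, n):
    return "".join(rng.choice(list("ARNDCEQGHILKMFPSTWYV"), n))


class TestSketchSimilarity:
    def test_identical_sequences(self):
        rng = np.random.default_rng(6)
        s = random_protein(rng, 100)
        assert sketch_similarity(s, s, k=5) == 1.0

    def test_disjoint_kmer_sets(self):
        assert sketch_similarity("A" * 50, "R" * 50, k=5) == 0.0

    def test_estimate_close_to_exact_jaccard(self):
        rng = np.random.default_rng(7)
        shared = random_protein(rng, 250)
        a = shared + random_protein(rng, 250)
        b = shared + random_protein(rng, 250)
        k = 21

        def kmers(s):
            return {s[i : i + k] for i in range(len(s) - k + 1)}

        exact = len(kmers(a) & kmers(b)) / len(kmers(a) | kmers(b))
        est = sketch_similarity(a, b, k=k, sketch_size=128)
        assert abs(est - exact) <= 0.06

    def test_symmetry_and_determinism(self):
        rng = np.random.default_rng(8)
        a, b = random_protein(rng, 80), random_protein(rng, 80)
        assert sketch_similarity(a, b, k=7) == sketch_similarity(b, a, k=7)
        assert sketch_similarity(a, b, k=7) == sketch_similarity(a, b, k=7)

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(EvaluationError):
            sketch_similarity("ARN", "ARNDCEQGHILKMFPSTWYVA", k=21)


class TestSimilarityAudit:
    def test_identical_phage_lands_in_top_bin(self):
        rng = np.random.default_rng(9)
        seq = random_protein(rng, 60)
        audit = similarity_audit(
            {"t1": seq}, {"tr1": seq}, [("t1", 1, 1)], k=7
        )
        assert audit.max_similarity["t1"] == 1.0
        assert audit.bin_counts == [0, 0, 0, 0, 1]

    def test_zero_similarity_lands_in_lowest_bin(self):
        audit = similarity_audit(
            {"t1": "A" * 30}, {"tr1": "R" * 30}, [("t1", 0, 0)], k=7
        )
        assert audit.bin_counts == [1, 0, 0, 0, 0]

    def test_hand_set_similarities_match_direct_histogram(self):
        sims = {"t0": 0.05, "t1": 0.15, "t2": 0.35, "t3": 0.55, "t4": 0.75,
                "t5": 0.95, "t6": 0.45, "t7": 0.25, "t8": 0.65, "t9": 0.85}
        # injected per-phage similarity: id strings double as lookup keys
        audit = similarity_audit(
            {t: t for t in sims},
            {"tr": "tr"},
            [(t, 1, 1) for t in sims],
            similarity_fn=lambda a, b: sims[a],
        )
        counts, _ = np.histogram(list(sims.values()), bins=5, range=(0, 1))
        assert audit.bin_counts == counts.tolist()
        assert sum(audit.bin_counts) == 10

    def test_per_bin_accuracy_and_empty_bins(self):
        sims = {"t0": 0.1, "t1": 0.9}
        audit = similarity_audit(
            {t: t for t in sims},
            {"tr": "tr"},
            [("t0", 1, 1), ("t0", 0, 1), ("t1", 1, 1)],
            similarity_fn=lambda a, b: sims[a],
        )
        assert audit.bin_pair_counts == [2, 0, 0, 0, 1]
        assert audit.bin_accuracy[0] == 0.5
        assert audit.bin_accuracy[1] is None
        assert audit.bin_accuracy[4] == 1.0


class TestLeakageFilter:
    def setup_method(self):
        self.negatives = [
            InteractionRecord("p1", "b1", label=0),
            InteractionRecord("p1", "b2", label=0),
            InteractionRecord("p2", "b1", label=0),
        ]
        self.train_seqs = {"p1": "p1", "p2": "p2"}
        self.test_seqs = {"t1": "t1"}
        self.sims = {("p1", "t1"): 0.95, ("p2", "t1"): 0.30}
        self.fn = lambda a, b: self.sims[(a, b)]

    def test_threshold_above_one_removes_nothing(self):
        kept, removed = leakage_filter(
            self.negatives, self.train_seqs, self.test_seqs, 1.01, similarity_fn=self.fn
        )
        assert kept == self.negatives and removed == []

    def test_threshold_zero_removes_everything(self):
        kept, removed = leakage_filter(
            self.negatives, self.train_seqs, self.test_seqs, 0.0, similarity_fn=self.fn
        )
        assert kept == [] and len(removed) == 3

    def test_mixed_thresholding_matches_max_similarity_check(self):
        kept, removed = leakage_filter(
            self.negatives, self.train_seqs, self.test_seqs, 0.9, similarity_fn=self.fn
        )
        assert [r.phage_id for r in kept] == ["p2"]
        assert {r["phage_id"] for r in removed} == {"p1"}
        assert all(r["max_similarity"] >= 0.9 for r in removed)
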