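"""Negative sampling, folds, metric suite and aggregation vs oracles."""

import numpy as np
import pytest

from nnps.evaluation import (
    SideEffectReport,
    aggregate,
    auprc,
    auroc,
    confusion_and_metrics,
    make_folds,
    metrics_from_counts,
    roc_curve,
    sample_negatives,
    select_threshold,
)
from nnps.io_ingest import EntityVocabulary
from nnps.neural_model import TrainTrace


def auroc_pair_oracle(y, p):
    """O(n^2) concordant-pair count, ties counted half."""
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
    return wins / (len(pos) * len(neg))


def auprc_sum_oracle(y, p):
    """Average precision by explicit summation over the score-sorted list.

    Examples are grouped by unique score (ties enter together), highest
    scores first; each group contributes (recall step) x (precision there).
    """
    order = np.argsort(-p, kind="stable")
    y, p = y[order], p[order]
    total_pos = y.sum()
    ap, tp, seen = 0.0, 0, 0
    i = 0
    while i < len(y):
        j = i
        while j < len(y) and p[j] == p[i]:
            j += 1
        group_tp = y[i:j].sum()
        tp += group_tp
        seen = j
        if group_tp:
            ap += (group_tp / total_pos) * (tp / seen)
        i = j
    return ap


class TestSampleNegatives:
    vocab = EntityVocabulary.from_ids("drug", ["A", "B", "C"])

    def test_enumerable_candidate_set(self):
        ex = sample_negatives([(0, 1)], self.vocab, ratio=1.0, seed=0)
        assert len(ex) == 2
        negs = {tuple(p) for p, l in zip(ex.pairs, ex.labels) if l == 0}
        assert negs <= {(0, 2), (1, 2)} and len(negs) == 1

    def test_balanced_sampling_disjoint_from_positives(self):
        rng = np.random.default_rng(0)
        n = 60
        all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        chosen = rng.choice(len(all_pairs), 500, replace=False)
        positives = [all_pairs[k] for k in chosen]
        ex = sample_negatives(positives, n, ratio=1.0, seed=1)
        assert len(ex) == 1000
        pos_set = set(positives)
        neg_set = {tuple(p) for p, l in zip(ex.pairs, ex.labels) if l == 0}
        assert len(neg_set) == 500
        assert not (neg_set & pos_set)

    def test_ratio_scales_negative_count(self):
        ex = sample_negatives([(i, i + 1) for i in range(0, 20, 2)], 30, ratio=2.0, seed=3)
        assert (ex.labels == 0).sum() == 20

    def test_same_seed_identical(self):
        a = sample_negatives([(0, 1)], 40, ratio=5.0, seed=9)
        b = sample_negatives([(0, 1)], 40, ratio=5.0, seed=9)
        np.testing.assert_array_equal(a.pairs, b.pairs)

    def test_insufficient_candidates_hard_error(self):
        with pytest.raises(ValueError, match="short by"):
            sample_negatives([(0, 1)], self.vocab, ratio=10.0, seed=0)

    def test_provenance_labels(self):
        ex = sample_negatives([(0, 1)], self.vocab, ratio=1.0, seed=0)
        assert ex.provenance == ["positive_source", "sampled_negative"]


class TestMakeFolds:
    def test_eighty_ten_ten(self):
        fa = make_folds(100, 5, seed=0)
        for split in fa.folds:
            assert len(split["train"]) == 80
            assert len(split["val"]) == 10
            assert len(split["test"]) == 10

    def test_partition_per_fold_and_across_folds(self):
        fa = make_folds(100, 5, seed=1)
        full = set(range(100))
        held_union = []
        for split in fa.folds:
            parts = [set(split[k]) for k in ("train", "val", "test")]
            assert set().union(*parts) == full
            assert sum(len(p) for p in parts) == 100
            held_union.extend(split["val"].tolist() + split["test"].tolist())
        assert sorted(held_union) == sorted(full)

    def test_remainder_rule_101_examples(self):
        fa = make_folds(101, 5, seed=2)
        sizes = sorted(
            (len(s["val"]), len(s["test"]), len(s["train"])) for s in fa.folds
        )
        # one fold holds 21 examples (val 10, test 11), four hold 20 (10/10)
        assert sizes == [(10, 10, 81)] * 4 + [(10, 11, 80)]

    def test_too_few_examples_or_folds(self):
        with pytest.raises(ValueError):
            make_folds(5, 5, seed=0)
        with pytest.raises(ValueError):
            make_folds(100, 1, seed=0)


class TestRankMetrics:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        assert auroc(y, p) == 1.0
        assert auprc(y, p) == 1.0

    def test_all_ties(self):
        y = np.array([0, 1, 0, 1, 1])
        p = np.full(5, 0.4)
        assert auroc(y, p) == 0.5
        assert abs(auprc(y, p) - 0.6) < 1e-12  # prevalence

    @pytest.mark.parametrize("seed", range(4))
    def test_auroc_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        p = np.round(rng.random(200), 2)  # rounding forces ties
        assert abs(auroc(y, p) - auroc_pair_oracle(y, p)) < 1e-10

    @pytest.mark.parametrize("seed", range(4))
    def test_auprc_matches_summation_oracle(self, seed):
        rng = np.random.default_rng(seed + 10)
        y = rng.integers(0, 2, 150)
        y[0] = 1
        p = rng.random(150)
        assert abs(auprc(y, p) - auprc_sum_oracle(y, p)) < 1e-12

    def test_single_class_is_hard_error(self):
        with pytest.raises(ValueError):
            auroc(np.ones(5), np.random.random(5))
        with pytest.raises(ValueError):
            roc_curve(np.zeros(5), np.random.random(5))
        with pytest.raises(ValueError):
            auprc(np.zeros(5), np.random.random(5))

    def test_auroc_negation_symmetry(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        p = rng.random(100)
        assert abs(auroc(y, p) - (1.0 - auroc(1 - y, p))) < 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        p = rng.random(80)
        perm = rng.permutation(80)
        assert auroc(y, p) == auroc(y[perm], p[perm])
        assert auprc(y, p) == auprc(y[perm], p[perm])
        a = confusion_and_metrics(y, p, 0.4)
        b = confusion_and_metrics(y[perm], p[perm], 0.4)
        assert a == b


class TestConfusion:
    def test_perfect_predictions(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.9, 0.8, 0.2, 0.1])
        m = confusion_and_metrics(y, p, 0.5)
        assert (m["precision"], m["recall"], m["f_score"], m["acc"], m["mcc"]) == (1, 1, 1, 1, 1)

    def test_hand_computed_counts(self):
        # TP=2, FP=1, TN=3, FN=0
        m = metrics_from_counts(2, 1, 3, 0)
        assert abs(m["precision"] - 2 / 3) < 1e-12
        assert m["recall"] == 1.0
        assert abs(m["f_score"] - 0.8) < 1e-12
        assert abs(m["acc"] - 5 / 6) < 1e-12
        assert abs(m["mcc"] - 6 / np.sqrt(72)) < 1e-12  # = 0.70711

    def test_all_predicted_negative_degenerate_zero(self):
        y = np.array([1, 0, 1])
        p = np.array([0.1, 0.1, 0.2])
        m = confusion_and_metrics(y, p, 0.9)
        assert m["tp"] == m["fp"] == 0
        assert m["precision"] == 0.0 and m["mcc"] == 0.0 and m["f_score"] == 0.0

    def test_strict_threshold_inequality(self):
        y = np.array([1, 0])
        p = np.array([0.5, 0.4])
        m = confusion_and_metrics(y, p, 0.5)
        assert m["tp"] == 0 and m["fn"] == 1  # p == theta is negative

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 40)
        p = rng.random(40)
        m = confusion_and_metrics(y, p, 0.3)
        assert m["tp"] + m["fp"] + m["tn"] + m["fn"] == 40


class TestSelectThreshold:
    def test_spec_of_four_examples(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.9, 0.8, 0.2, 0.1])
        theta = select_threshold(y, p)
        assert theta == 0.2
        assert confusion_and_metrics(y, p, theta)["f_score"] == 1.0

    def test_all_positive_returns_zero(self):
        y = np.ones(4)
        p = np.array([0.3, 0.6, 0.9, 0.2])
        theta = select_threshold(y, p)
        assert theta == 0.0
        assert confusion_and_metrics(y, p, theta)["f_score"] == 1.0

    def test_no_positives_falls_back(self):
        with pytest.warns(UserWarning, match="theta=0.5"):
            assert select_threshold(np.zeros(4), np.random.random(4)) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        p = np.round(rng.random(60), 2)
        theta = select_threshold(y, p)
        candidates = np.concatenate([[0.0], np.unique(p)])
        fs = [confusion_and_metrics(y, p, t)["f_score"] for t in candidates]
        best = max(fs)
        assert confusion_and_metrics(y, p, theta)["f_score"] == best
        # tie-break: no larger candidate achieves the same F-score
        larger = [t for t, f in zip(candidates, fs) if f == best]
        assert theta == max(larger)

    def test_never_worse_than_default_half(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            y[:2] = [0, 1]
            p = rng.random(30)
            theta = select_threshold(y, p)
            assert (
                confusion_and_metrics(y, p, theta)["f_score"]
                >= confusion_and_metrics(y, p, 0.5)["f_score"]
            )


def report(sid, theta, auroc_v, **kw):
    base = dict(tp=5, fp=1, tn=4, fn=0, precision=0.8, recall=1.0,
                f_score=0.9, acc=0.9, mcc=0.8, auprc=0.9)
    base.update(kw)
    return SideEffectReport(side_effect=sid, theta=theta, auroc=auroc_v, **base)


class TestAggregate:
    def test_single_report_identity(self):
        r = report("S1", 0.4, 0.9)
        agg = aggregate([r])
        assert agg.theta_mean == 0.4 and agg.theta_sd == 0.0
        assert agg.metric_means["auroc"] == 0.9
        assert agg.pooled_counts == {"tp": 5, "fp": 1, "tn": 4, "fn": 0}

    def test_two_reports_average(self):
        agg = aggregate([report("S1", 0.4, 0.8), report("S2", 0.6, 1.0)])
        assert abs(agg.metric_means["auroc"] - 0.9) < 1e-15
        assert abs(agg.theta_mean - 0.5) < 1e-15

    def test_mean_sd_match_two_pass_oracle(self):
        rng = np.random.default_rng(3)
        thetas = rng.random(5)
        reports = [report(f"S{i}", float(t), 0.9) for i, t in enumerate(thetas)]
        agg = aggregate(reports)
        mean = sum(thetas) / 5
        sd = np.sqrt(sum((t - mean) ** 2 for t in thetas) / 4)
        assert abs(agg.theta_mean - mean) < 1e-12
        assert abs(agg.theta_sd - sd) < 1e-12

    def test_epoch_traces_averaged(self):
        t1 = TrainTrace([1.0, 0.5], [1.0, 0.6], [0.7, 0.8])
        t2 = TrainTrace([0.8, 0.4], [0.9, 0.5], [0.9, 1.0])
        agg = aggregate([report("S1", 0.5, 0.9), report("S2", 0.5, 0.9)], [t1, t2])
        assert agg.mloss == [0.9, 0.45]
        assert agg.mauroc == [0.8, 0.9]

    def test_mismatched_epoch_counts_rejected(self):
        t1 = TrainTrace([1.0], [1.0], [0.5])
        t2 = TrainTrace([1.0, 0.9], [1.0, 0.9], [0.5, 0.6])
        with pytest.raises(ValueError, match="epoch"):
            aggregate([report("S1", 0.5, 0.9), report("S2", 0.5, 0.9)], [t1, t2])
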