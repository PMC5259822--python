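"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morfhmm.evaluation import (
    SingleClassError,
    accuracy_at_tpr,
    evaluate,
    fpr_at_tpr,
    roc_auc,
    success_rate,
)


def pairwise_auc(scores, labels):
    """Brute-force Mann-Whitney statistic: P(pos > neg), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = rng.random(n)
        if rng.random() < 0.5:
            scores = np.round(scores, 1)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-12
        )

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(40)
        labels = np.r_[np.ones(20, int), np.zeros(20, int)]
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc(np.exp(3 * scores), labels), abs=1e-12
        )


class TestFprAtTpr:
    def test_perfect_separation_zero_fpr(self):
        assert fpr_at_tpr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.222) == 0.0

    def test_enumerated_threshold_example(self):
        # threshold 0.9 is the largest cutoff with TPR >= 0.5; FPR there is 0
        assert fpr_at_tpr([0.9, 0.7, 0.6, 0.4], [1, 0, 1, 0], 0.5) == 0.0

    def test_anti_separated_at_full_tpr(self):
        assert fpr_at_tpr([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], 1.0) == 1.0

    def test_non_decreasing_in_level(self):
        rng = np.random.default_rng(4)
        scores = rng.random(200)
        labels = rng.integers(0, 2, size=200)
        levels = np.linspace(0.05, 1.0, 20)
        fprs = [fpr_at_tpr(scores, labels, lv) for lv in levels]
        assert all(b >= a for a, b in zip(fprs, fprs[1:]))

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            fpr_at_tpr([0.1, 0.9], [0, 1], 0.0)


class TestAccuracyAtTpr:
    def test_perfect_separation_at_separating_threshold(self):
        # TPR level 1.0 places the threshold at the class boundary
        assert accuracy_at_tpr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0) == 1.0

    def test_imbalanced_low_tpr(self):
        """1 positive among 100; catching it at a clean threshold keeps TN high."""
        scores = np.r_[0.99, np.linspace(0.0, 0.5, 99)]
        labels = np.r_[1, np.zeros(99, int)]
        assert accuracy_at_tpr(scores, labels, 0.01) == 1.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_confusion_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(80)
        labels = rng.integers(0, 2, size=80)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        level = float(rng.uniform(0.1, 1.0))
        # oracle: enumerate candidate thresholds from the score set
        best_thr = None
        pos = scores[labels == 1]
        for thr in sorted(set(scores), reverse=True):
            if np.mean(pos >= thr) >= level:
                best_thr = thr
                break
        pred = scores >= best_thr
        tp = np.sum(pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        assert accuracy_at_tpr(scores, labels, level) == pytest.approx(
            (tp + tn) / len(labels)
        )


class TestSuccessRate:
    def test_all_separated(self):
        seqs = [
            (np.array([0.9, 0.9, 0.1]), np.array([1, 1, 0])),
            (np.array([0.7, 0.2, 0.2]), np.array([1, 0, 0])),
        ]
        assert success_rate(seqs) == 1.0

    def test_constant_scores_fail_strict_comparison(self):
        seqs = [(np.full(10, 0.3), np.r_[np.ones(3, int), np.zeros(7, int)])]
        assert success_rate(seqs) == 0.0

    def test_two_of_three(self):
        good = (np.array([0.9, 0.1]), np.array([1, 0]))
        bad = (np.array([0.1, 0.9]), np.array([1, 0]))
        assert success_rate([good, good, bad]) == pytest.approx(2 / 3)

    def test_single_class_sequences_excluded(self):
        good = (np.array([0.9, 0.1]), np.array([1, 0]))
        no_morf = (np.array([0.5, 0.5]), np.array([0, 0]))
        assert success_rate([good, no_morf]) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            success_rate([])


def test_full_report_consistency():
    rng = np.random.default_rng(2)
    per_seq = []
    for _ in range(5):
        n = int(rng.integers(20, 50))
        labels = np.zeros(n, dtype=int)
        labels[: n // 4] = 1
        scores = np.clip(labels * 0.5 + rng.normal(0.3, 0.15, n), 0, 1)
        per_seq.append((scores, labels))
    rep = evaluate(per_seq)
    assert 0.0 <= rep.auc <= 1.0
    assert 0.0 <= rep.success_rate <= 1.0
    assert set(rep.fpr_at_tpr) == {0.222, 0.389}
    assert rep.n_pos + rep.n_neg == sum(len(s) for s, _ in per_seq)
    assert rep.fpr_at_tpr[0.222] <= rep.fpr_at_tpr[0.389]
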