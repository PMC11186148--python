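"""Metric implementations vs. brute-force oracles and library cross-checks."""

import itertools

import numpy as np
import pytest

from molenc import metrics
from molenc.metrics import (UndefinedMetricError, auprc, auroc, f1_scores,
                            mae, recovery_accuracy, spearman)


def brute_force_auroc(scores, labels):
    """Pair enumeration: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def brute_force_spearman(a, b):
    """Rank both vectors (average ranks) and take the Pearson correlation."""
    def ranks(x):
        x = np.asarray(x, dtype=float)
        r = np.empty(len(x))
        for i, v in enumerate(x):
            less = (x < v).sum()
            equal = (x == v).sum()
            r[i] = less + (equal + 1) / 2.0
        return r

    ra, rb = ranks(a), ranks(b)
    return float(np.corrcoef(ra, rb)[0, 1])


class TestRecoveryAccuracy:
    @pytest.mark.parametrize("pred, tgt, pos, expected", [
        ([9, 1, 2, 3, 9], [1, 2, 3], [1, 2, 3], 1.0),
        ([9, 5, 5, 5, 9], [1, 2, 3], [1, 2, 3], 0.0),
        ([0, 1, 2, 9, 4, 9], [1, 2, 3, 4, 5], [1, 2, 3, 4, 5], 0.6),
    ])
    def test_fraction_rule(self, pred, tgt, pos, expected):
        assert recovery_accuracy(pred, tgt, pos) == expected

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            recovery_accuracy([1], [], [])


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_give_half(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_four_point_case_vs_pair_enumeration(self):
        scores, labels = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        assert auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.9], [1, 1])

    def test_complement_symmetry_without_ties(self, rng):
        scores = rng.permutation(20) / 20.0
        labels = rng.integers(0, 2, 20)
        labels[0], labels[1] = 0, 1
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0)


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_give_prevalence(self):
        assert auprc([0.3] * 8, [1, 0, 0, 1, 0, 0, 0, 0]) == pytest.approx(0.25)

    def test_four_point_case_vs_hand_path(self):
        # descending: 0.8(1), 0.4(0), 0.35(1), 0.1(0)
        # recall steps: 1/2 at P=1, 2/2 at P=2/3
        expected = 0.5 * 1.0 + 0.5 * (2 / 3)
        assert auprc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(expected)

    def test_no_positives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auprc([0.1, 0.9], [0, 0])


class TestMaeSpearman:
    def test_mae_cases(self):
        assert mae([1, 2, 3], [1, 2, 3]) == 0.0
        assert mae([2, 3, 4], [1, 2, 3]) == 1.0
        assert mae([1.0, 2.5, 2.0], [2.0, 2.0, 4.0]) == pytest.approx(
            (1.0 + 0.5 + 2.0) / 3)

    def test_spearman_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
        assert spearman([4, 3, 2, 1], [10, 20, 30, 40]) == pytest.approx(-1.0)

    def test_spearman_ties_vs_rank_formula(self):
        a, b = [1.0, 2.0, 2.0, 3.0], [1.0, 3.0, 2.0, 4.0]
        assert spearman(a, b) == pytest.approx(brute_force_spearman(a, b))


class TestF1:
    def test_perfect_predictions(self):
        y = np.array([[1, 0, 1], [0, 1, 0]])
        p = y.astype(float) * 0.9 + 0.05
        assert f1_scores(p, y) == (1.0, 1.0)

    def test_all_negative_predictions(self):
        y = np.array([[1, 0], [1, 1]])
        p = np.full((2, 2), 0.1)
        assert f1_scores(p, y) == (0.0, 0.0)

    def test_three_label_toy_vs_hand_counts(self):
        p = np.array([[0.9, 0.2, 0.6],
                      [0.8, 0.7, 0.4],
                      [0.1, 0.6, 0.9]])
        y = np.array([[1, 0, 0],
                      [0, 1, 1],
                      [0, 1, 1]])
        # label0: tp=1 fp=1 fn=0 -> f1=2/3; label1: tp=2 fp=0 fn=0 -> 1.0
        # label2: tp=1 fp=1 fn=1 -> 0.5
        macro = (2 / 3 + 1.0 + 0.5) / 3
        micro = 2 * 4 / (2 * 4 + 2 + 1)
        got_macro, got_micro = f1_scores(p, y)
        assert got_macro == pytest.approx(macro)
        assert got_micro == pytest.approx(micro)

    def test_zero_support_label_contributes_zero_macro(self):
        y = np.array([[1, 0], [1, 0]])
        p = np.array([[0.9, 0.1], [0.9, 0.1]])
        macro, micro = f1_scores(p, y)
        assert macro == 0.5 and micro == 1.0

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            f1_scores(np.array([[0.5]]), np.array([[1]]), threshold=1.5)


class TestLibraryCrossChecks:
    """100 random cases per metric vs. scikit-learn / SciPy to 1e-9."""

    def test_auroc_vs_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.random(n), 2)  # induce ties
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            assert auroc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-9)

    def test_auprc_vs_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            labels[0] = 1
            assert auprc(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-9)

    def test_spearman_vs_scipy(self):
        from scipy.stats import spearmanr
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            a = np.round(rng.random(n), 1)
            b = np.round(rng.random(n), 1)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            assert spearman(a, b) == pytest.approx(
                spearmanr(a, b).statistic, abs=1e-9)

    def test_f1_vs_sklearn(self):
        from sklearn.metrics import f1_score
        rng = np.random.default_rng(3)
        for _ in range(100):
            n, k = int(rng.integers(3, 30)), int(rng.integers(2, 6))
            p = rng.random((n, k))
            y = rng.integers(0, 2, (n, k))
            macro, micro = f1_scores(p, y)
            assert macro == pytest.approx(
                f1_score(y, p >= 0.5, average="macro", zero_division=0),
                abs=1e-9)
            assert micro == pytest.approx(
                f1_score(y, p >= 0.5, average="micro", zero_division=0),
                abs=1e-9)


class TestInvariances:
    def test_permutation_invariance(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        perm = rng.permutation(30)
        assert auroc(scores, labels) == pytest.approx(auroc(scores[perm], labels[perm]))
        assert auprc(scores, labels) == pytest.approx(auprc(scores[perm], labels[perm]))
        assert mae(scores, labels) == pytest.approx(mae(scores[perm], labels[perm]))
        assert spearman(scores, labels) == pytest.approx(
            spearman(scores[perm], labels[perm]))

    def test_report_record(self):
        rep = metrics.MetricReport("AUROC", [0.8, 0.9])
        assert rep.mean == pytest.approx(0.85)
        assert "mean\t0.850000" in rep.to_record()
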