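import numpy as np
import pytest
from scipy import stats

from neurospect import (
    ConfusionMatrix3,
    accuracy,
    confusion_matrix,
    precision,
    roc_one_vs_rest,
    sensitivity,
    summarize,
)
from neurospect.evaluation import DegenerateRocError, as_percent, round_half_up


def cm_from_diagonal(diag, row_total=64):
    """3x3 matrix with given diagonal; off-diagonal spread over the other
    two columns (placement irrelevant to row-based metrics)."""
    counts = np.zeros((3, 3), dtype=np.int64)
    for i, d in enumerate(diag):
        counts[i, i] = d
        rest = row_total - d
        others = [j for j in range(3) if j != i]
        counts[i, others[0]] = rest // 2
        counts[i, others[1]] = rest - rest // 2
    return ConfusionMatrix3(counts)


class TestRounding:
    def test_half_up(self):
        assert round_half_up(79.65, 1) == 79.7
        assert round_half_up(79.64, 1) == 79.6
        assert as_percent(51 / 64) == 79.7


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = np.array([1, 2, 3] * 10)
        cm = confusion_matrix(y, y)
        assert np.array_equal(cm.counts, np.diag([10, 10, 10]))
        assert accuracy(cm) == 1.0

    def test_single_misclassification(self):
        cm = confusion_matrix([1], [2])
        expected = np.zeros((3, 3), int)
        expected[0, 1] = 1
        assert np.array_equal(cm.counts, expected)

    def test_random_labels_match_counting_oracle(self, rng):
        y_true = rng.integers(1, 4, 300)
        y_pred = rng.integers(1, 4, 300)
        cm = confusion_matrix(y_true, y_pred)
        for i in range(1, 4):
            for j in range(1, 4):
                manual = sum(1 for t, p in zip(y_true, y_pred) if t == i and p == j)
                assert cm.counts[i - 1, j - 1] == manual
        assert cm.n == 300

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([1, 4], [1, 1])

    def test_conservation(self, rng):
        y_true = rng.integers(1, 4, 200)
        y_pred = rng.integers(1, 4, 200)
        cm = confusion_matrix(y_true, y_pred)
        assert cm.counts.sum() == 200
        for c in (1, 2, 3):
            assert cm.row(c).sum() == np.sum(y_true == c)


class TestSensitivityPrecisionAccuracy:
    def test_worked_mci_row(self):
        cm = cm_from_diagonal([51, 46, 40])
        assert as_percent(sensitivity(cm, 1)) == 79.7

    def test_worked_ad_row(self):
        cm = cm_from_diagonal([51, 46, 40])
        assert as_percent(sensitivity(cm, 2)) == 71.9

    def test_worked_hc_row(self):
        cm = cm_from_diagonal([51, 46, 40])
        assert as_percent(sensitivity(cm, 3)) == 62.5

    def test_worked_overall_accuracy(self):
        cm = cm_from_diagonal([51, 46, 40])
        assert accuracy(cm) == pytest.approx(137 / 192)
        assert as_percent(accuracy(cm)) == 71.4

    def test_precision_column_arithmetic(self):
        counts = np.zeros((3, 3), dtype=np.int64)
        counts[:, 0] = [51, 20, 9]  # predicted-MCI column
        counts[0, 1] = 13
        counts[1, 1] = 44
        counts[2, 2] = 55
        cm = ConfusionMatrix3(counts)
        assert precision(cm, 1) == pytest.approx(51 / 80)
        assert as_percent(precision(cm, 1)) == 63.7

    def test_diagonal_matrix_perfect(self):
        cm = ConfusionMatrix3(np.diag([5, 6, 7]))
        for c in (1, 2, 3):
            assert sensitivity(cm, c) == 1.0
            assert precision(cm, c) == 1.0

    def test_single_off_diagonal_zero_precision(self):
        counts = np.zeros((3, 3), dtype=np.int64)
        counts[0, 1] = 4
        counts[1, 2] = 1
        counts[2, 2] = 1
        cm = ConfusionMatrix3(counts)
        assert precision(cm, 2) == 0.0

    def test_empty_row_and_column_errors(self):
        counts = np.zeros((3, 3), dtype=np.int64)
        counts[0, 0] = 5
        counts[1, 0] = 2
        counts[2, 0] = 1
        cm = ConfusionMatrix3(counts)
        with pytest.raises(ValueError):
            precision(cm, 2)

    def test_all_wrong_zero_accuracy(self):
        counts = np.zeros((3, 3), dtype=np.int64)
        counts[0, 1] = counts[1, 2] = counts[2, 0] = 10
        assert accuracy(ConfusionMatrix3(counts)) == 0.0

    def test_uniform_random_near_third(self, rng):
        y_true = rng.integers(1, 4, 3000)
        y_pred = rng.integers(1, 4, 3000)
        assert accuracy(confusion_matrix(y_true, y_pred)) == pytest.approx(1 / 3, abs=0.03)

    def test_accuracy_is_sensitivity_weighted_identity(self, rng):
        y_true = rng.integers(1, 4, 500)
        y_pred = rng.integers(1, 4, 500)
        cm = confusion_matrix(y_true, y_pred)
        weighted = sum(sensitivity(cm, c) * cm.row(c).sum() / cm.n for c in (1, 2, 3))
        assert accuracy(cm) == pytest.approx(weighted, abs=1e-12)


def random_scores(rng, n):
    s = rng.dirichlet(np.ones(3), size=n)
    return s


class TestRoc:
    def test_perfect_separation_auc_one(self):
        y = np.array([1] * 5 + [2] * 5 + [3] * 5)
        scores = np.full((15, 3), 0.05)
        for i, label in enumerate(y):
            scores[i, label - 1] = 0.9
        for c in (1, 2, 3):
            assert roc_one_vs_rest(y, scores, c).auc == pytest.approx(1.0)

    def test_label_independent_scores_auc_half(self, rng):
        y = rng.integers(1, 4, 1000)
        scores = random_scores(rng, 1000)
        roc = roc_one_vs_rest(y, scores, 1)
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_normalized_rank_sum(self, rng):
        """Trapezoid AUC == Mann-Whitney U / (n_pos * n_neg) on 50 random
        instances (scipy rank-sum oracle)."""
        for _ in range(50):
            n = int(rng.integers(20, 80))
            y = rng.integers(1, 4, n)
            if len(np.unique(y)) < 2 or np.sum(y == 1) in (0, n):
                continue
            scores = random_scores(rng, n)
            roc = roc_one_vs_rest(y, scores, 1)
            pos = scores[y == 1, 0]
            neg = scores[y != 1, 0]
            u_stat = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert roc.auc == pytest.approx(u_stat / (len(pos) * len(neg)), abs=1e-9)

    def test_monotone_staircase(self, rng):
        y = rng.integers(1, 4, 200)
        roc = roc_one_vs_rest(y, random_scores(rng, 200), 2)
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert 0.0 <= roc.auc <= 1.0

    def test_one_class_degenerate(self, rng):
        y = np.ones(10, dtype=int)
        with pytest.raises(DegenerateRocError):
            roc_one_vs_rest(y, random_scores(rng, 10), 1)


class TestSummarize:
    def test_identity_predictions(self, rng):
        y = np.array([1, 2, 3] * 13)
        scores = np.full((39, 3), 0.05)
        for i, label in enumerate(y):
            scores[i, label - 1] = 0.9
        cm = confusion_matrix(y, y)
        rocs = {c: roc_one_vs_rest(y, scores, c) for c in (1, 2, 3)}
        report = summarize(cm, rocs, "knn")
        for c in (1, 2, 3):
            assert report.sensitivity_pct[c] == 100.0
            assert report.precision_pct[c] == 100.0
            assert report.auc[c] == pytest.approx(1.0)
        assert report.accuracy_pct == 100.0
        assert report.macro_auc == pytest.approx(1.0)

    def test_miss_rate_identity(self, rng):
        y_true = rng.integers(1, 4, 120)
        y_pred = rng.integers(1, 4, 120)
        report = summarize(confusion_matrix(y_true, y_pred), None, "lda")
        for c in (1, 2, 3):
            assert report.miss_rate_pct[c] == pytest.approx(
                100.0 - report.sensitivity_pct[c], abs=0.051
            )

    def test_table_row_shape(self):
        cm = cm_from_diagonal([51, 46, 40])
        report = summarize(cm, None, "knn").to_dict()
        for key in ("sensitivity_pct", "precision_pct", "auc"):
            assert set(report[key]) == {"MCI", "AD", "HC"}
        assert "accuracy_pct" in report and "macro_auc" in report
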