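"""Metrics (confusion, sensitivity/specificity, BACC, AUROC) and the
statistical comparison protocol (paired t, Kruskal-Wallis with Dunn)."""

import numpy as np
import pytest

from lesiondag import (
    auroc_one_vs_rest,
    bacc,
    binarize,
    confusion,
    kruskal_dunn,
    metrics_report,
    paired_t,
    root_sweep,
    select_root,
    sensitivity,
    specificity,
)
from .conftest import condorcet_score_set, random_score_set


class TestBinarize:
    def test_binary_threshold(self):
        probs = np.array([[0.7, 0.3], [0.5, 0.5], [0.2, 0.8]])
        # positive class is column 0; boundary 0.5 counts as positive
        assert binarize(probs, 0.5).tolist() == [0, 0, 1]

    def test_multiclass_argmax(self):
        assert binarize(np.array([[0.2, 0.5, 0.3]])).tolist() == [1]


class TestConfusion:
    def test_hand_tally(self):
        cm = confusion([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 1]])

    def test_perfect_predictions_diagonal(self):
        y = np.array([0, 1, 2, 2, 1])
        cm = confusion(y, y, 3)
        assert np.array_equal(cm, np.diag([1, 2, 2]))

    def test_total_is_sample_count(self, rng):
        y_true = rng.integers(3, size=40)
        y_pred = rng.integers(3, size=40)
        assert confusion(y_true, y_pred, 3).sum() == 40

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 3], [0, 1], 3)


class TestSensitivitySpecificityBacc:
    def test_sensitivity_hand_value(self):
        cm = np.array([[8, 2], [1, 9]])
        assert sensitivity(cm, 0) == pytest.approx(0.8)
        assert specificity(cm, 0) == pytest.approx(0.9)

    def test_binary_bacc_closed_form(self):
        # TP=8, FN=2, TN=9, FP=1 -> (0.8 + 0.9) / 2
        assert bacc(np.array([[8, 2], [1, 9]])) == pytest.approx(0.85)

    def test_perfect_classifier(self):
        assert bacc(np.diag([5, 7, 3])) == 1.0

    def test_constant_predictor_on_balanced_binary(self):
        cm = confusion([0] * 10 + [1] * 10, [0] * 20, 2)
        assert bacc(cm) == pytest.approx(0.5)

    def test_absent_predicted_class_zero_sensitivity(self):
        cm = confusion([0, 0, 1], [1, 1, 1], 2)
        assert sensitivity(cm, 0) == 0.0

    def test_empty_true_class_rejected(self):
        with pytest.raises(ValueError):
            sensitivity(np.array([[0, 0], [1, 1]]), 0)

    def test_bacc_equals_accuracy_on_balanced_set(self, rng):
        y_true = np.repeat([0, 1, 2], 30)
        y_pred = rng.integers(3, size=90)
        cm = confusion(y_true, y_pred, 3)
        assert bacc(cm) == pytest.approx(float((y_true == y_pred).mean()), abs=1e-12)

    def test_random_predictor_macro_bacc_near_chance(self, rng):
        # imbalanced truth, uniform predictions: expect 1/K
        y_true = np.repeat([0, 1, 2], [50, 400, 50])
        baccs = [
            bacc(confusion(y_true, rng.integers(3, size=500), 3)) for _ in range(200)
        ]
        assert abs(np.mean(baccs) - 1 / 3) < 3 * np.std(baccs) / np.sqrt(200)


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc_one_vs_rest([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_identical_scores_half(self):
        assert auroc_one_vs_rest([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_hand_example(self):
        assert auroc_one_vs_rest([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.uniform(size=60).round(1)  # coarse grid forces ties
        truth = rng.integers(2, size=60)
        if len(np.unique(truth)) < 2:
            truth[0] = 1 - truth[0]
        pos = scores[truth == 1]
        neg = scores[truth == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        assert auroc_one_vs_rest(scores, truth) == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(size=50)
        truth = np.r_[np.ones(25, int), np.zeros(25, int)]
        a = auroc_one_vs_rest(scores, truth)
        b = auroc_one_vs_rest(np.exp(5 * scores), truth)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc_one_vs_rest([0.1, 0.2], [1, 1])


class TestMetricsReport:
    def test_report_fields_consistent(self, rng):
        probs = rng.dirichlet(np.ones(3), size=120)
        y_true = rng.integers(3, size=120)
        report = metrics_report(y_true, probs)
        assert report.confusion.sum() == 120
        assert 0.0 <= report.bacc <= 1.0
        assert set(report.sensitivity) == {0, 1, 2}
        assert all(0 <= v <= 1 for v in report.auroc.values())
        assert report.threshold == 0.5


class TestPairedT:
    def test_identical_vectors_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            paired_t(a, a)

    def test_constant_difference_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            paired_t(a, a + 0.5)

    def test_detects_shift(self, rng):
        a = rng.normal(size=100)
        _, p = paired_t(a, a + 1.0 + rng.normal(scale=0.1, size=100))
        assert p < 1e-6

    def test_type_one_error_calibrated(self):
        """Exchangeable pairs: rejection rate at alpha=0.05 within 3 sigma."""
        rng = np.random.default_rng(7)
        reps, n, alpha = 1000, 200, 0.05
        rejections = 0
        for _ in range(reps):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            _, p = paired_t(a, b)
            rejections += p < alpha
        rate = rejections / reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)


class TestKruskalDunn:
    def test_identical_groups_share_rank(self):
        g = [np.array([1.0, 1.0, 1.0])] * 3
        result = kruskal_dunn(g)
        assert result.omnibus_p >= 0.99
        assert set(result.group_ranks.values()) == {1}
        assert all(len(s) == 0 for s in result.worse_than.values())

    def test_clearly_separated_group_dominates(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(10, 0.1, 30), rng.normal(0, 0.1, 30), rng.normal(0, 0.1, 30)]
        result = kruskal_dunn(groups, names=["a", "b", "c"])
        assert result.group_ranks["a"] == 1
        assert result.worse_than["a"] == {"b", "c"}
        assert result.group_ranks["b"] == result.group_ranks["c"] == 2

    def test_can_express_strict_total_order(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(mu, 0.1, 30) for mu in (6.0, 3.0, 0.0)]
        result = kruskal_dunn(groups)
        assert sorted(result.group_ranks.values()) == [1, 2, 3]

    def test_omnibus_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        reps, alpha = 1000, 0.05
        rejections = sum(
            kruskal_dunn([rng.normal(size=30) for _ in range(3)]).omnibus_p < alpha
            for _ in range(reps)
        )
        rate = rejections / reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn([np.ones(5), np.zeros(5)])


class TestRootSweep:
    def test_condorcet_configuration_root_invariant(self, rng):
        sets, winners = [], []
        for _ in range(60):
            s, w = condorcet_score_set(rng, 3)
            sets.append(s)
            winners.append(w)
        table = root_sweep(sets, np.array(winners), 3)
        assert len(table) == 3
        assert len({round(v, 12) for v in table.values()}) == 1

    def test_selected_root_attains_sweep_max(self, rng):
        sets = [random_score_set(rng, 3) for _ in range(200)]
        y = rng.integers(3, size=200)
        table = root_sweep(sets, y, 3)
        chosen = select_root(table)
        assert table[chosen.root_pair] == max(table.values())
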