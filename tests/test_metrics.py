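import numpy as np
import pytest

from cliffpix.errors import DataError, UsageError
from cliffpix.metrics import (
    ConfusionCounts,
    accuracy,
    accuracy_tp_fn_variant,
    aggregate,
    auc_single_point,
    balanced_accuracy,
    confusion,
    f1,
    mcc,
    report,
    roc_auc,
)


def concordance_auc(scores, labels):
    """Pair-counting oracle: P(score_pos > score_neg), ties count half."""
    pos = [s for s, l in zip(scores, labels) if l == "AC"]
    neg = [s for s, l in zip(scores, labels) if l == "NON_AC"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions(self):
        c = confusion(["AC"] * 3 + ["NON_AC"] * 5, ["AC"] * 3 + ["NON_AC"] * 5)
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 5, 0, 0)

    def test_majority_only_predictions(self):
        c = confusion(["AC"] * 3 + ["NON_AC"] * 5, ["NON_AC"] * 8)
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 5, 0, 3)

    def test_empty_vectors(self):
        c = confusion([], [])
        assert c.total == 0

    def test_length_mismatch(self):
        with pytest.raises(UsageError):
            confusion(["AC"], [])

    def test_unknown_label(self):
        with pytest.raises(UsageError):
            confusion(["AC"], ["maybe"])


class TestFormulas:
    def test_perfect_classifier(self):
        c = ConfusionCounts(3, 5, 0, 0)
        assert mcc(c) == pytest.approx(1.0)
        assert f1(c) == pytest.approx(1.0)
        assert accuracy(c) == pytest.approx(1.0)
        assert balanced_accuracy(c) == pytest.approx(1.0)

    def test_chance_level_symmetric_table(self):
        c = ConfusionCounts(2, 2, 2, 2)
        assert mcc(c) == pytest.approx(0.0)
        assert balanced_accuracy(c) == pytest.approx(0.5)

    def test_hand_worked_table(self):
        c = ConfusionCounts(8, 1, 2, 1)
        assert mcc(c) == pytest.approx((8 * 1 - 2 * 1) / np.sqrt(10 * 9 * 3 * 2))
        assert f1(c) == pytest.approx(16 / 19)
        assert balanced_accuracy(c) == pytest.approx((8 / 9 + 1 / 3) / 2)
        assert accuracy(c) == pytest.approx(9 / 12)
        assert accuracy_tp_fn_variant(c) == pytest.approx(9 / 12)  # here TP+FN == TP+TN

    def test_zero_denominators_return_zero(self):
        c = ConfusionCounts(0, 4, 0, 0)  # no positives at all
        assert mcc(c) == 0.0
        assert f1(c) == 0.0
        assert balanced_accuracy(c) == pytest.approx(0.5)  # sens 0 conv., spec 1

    def test_label_swap_negates_mcc_on_balanced_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            c = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            swapped = ConfusionCounts(int(fn), int(fp), int(tn), int(tp))
            assert mcc(swapped) == pytest.approx(-mcc(c), abs=1e-12)

    def test_matches_sklearn_on_random_tables(self):
        from sklearn.metrics import (
            accuracy_score,
            balanced_accuracy_score,
            f1_score,
            matthews_corrcoef,
        )

        rng = np.random.default_rng(42)
        for _ in range(200):
            counts = rng.integers(0, 20, size=4)
            if counts.sum() == 0 or counts[0] + counts[3] == 0 or counts[1] + counts[2] == 0:
                continue
            tp, tn, fp, fn = (int(v) for v in counts)
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            c = ConfusionCounts(tp, tn, fp, fn)
            assert accuracy(c) == pytest.approx(accuracy_score(y_true, y_pred))
            assert f1(c) == pytest.approx(f1_score(y_true, y_pred, zero_division=0))
            assert mcc(c) == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)
            if tp + fn and tn + fp:
                assert balanced_accuracy(c) == pytest.approx(
                    balanced_accuracy_score(y_true, y_pred)
                )


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], ["AC", "AC", "NON_AC", "NON_AC"])
        assert auc == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5] * 6, ["AC", "AC", "NON_AC", "NON_AC", "NON_AC", "NON_AC"])
        assert auc == pytest.approx(0.5)

    def test_single_inversion_matches_pair_counting(self):
        scores = [0.9, 0.3, 0.8, 0.4, 0.2, 0.1]
        labels = ["AC", "AC", "NON_AC", "NON_AC", "NON_AC", "NON_AC"]
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(concordance_auc(scores, labels))

    def test_matches_concordance_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(4, 50))
            labels = ["AC" if v else "NON_AC" for v in rng.integers(0, 2, size=n)]
            if "AC" not in labels or "NON_AC" not in labels:
                continue
            # quantized scores force plenty of ties
            scores = np.round(rng.random(n), 1)
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(concordance_auc(scores, labels), abs=1e-12)

    def test_roc_points_are_monotone(self):
        rng = np.random.default_rng(3)
        labels = ["AC" if v else "NON_AC" for v in rng.integers(0, 2, size=30)]
        _, points = roc_auc(rng.random(30), labels)
        fpr, tpr = zip(*points)
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_single_class_truth_is_data_error(self):
        with pytest.raises(DataError):
            roc_auc([0.1, 0.2], ["AC", "AC"])

    def test_single_point_surrogate_equals_balanced_accuracy(self):
        c = ConfusionCounts(8, 1, 2, 1)
        assert auc_single_point(c) == pytest.approx(balanced_accuracy(c))


class TestAggregate:
    def _rep(self, auc):
        return report(
            ["AC", "NON_AC"], ["AC", "NON_AC"], [auc, 0.1]
        )

    def test_identical_reports_have_zero_sd(self):
        reports = [self._rep(0.9)] * 10
        agg = aggregate(reports)
        assert agg.n_trials == 10
        assert all(v == 0.0 for v in agg.sd.values())

    def test_mean_of_two_values(self):
        a = report(["AC", "NON_AC"], ["AC", "NON_AC"], [0.9, 0.1])
        b = report(["AC", "NON_AC"], ["AC", "AC"], [0.9, 0.1])
        agg = aggregate([a, b])
        assert agg.mean["accuracy"] == pytest.approx(0.75)

    def test_matches_hand_computed_sample_sd(self):
        vals = [0.9, 1.0, 0.8]
        reps = []
        for v in vals:
            reps.append(
                report(["AC", "NON_AC"], ["AC", "NON_AC"], [v, v - 0.5])
            )
        # all reports are perfect classifications; sd of accuracy is 0
        agg = aggregate(reps)
        assert agg.mean["accuracy"] == pytest.approx(1.0)
        assert agg.sd["accuracy"] == pytest.approx(0.0)
        # sample sd on raw numbers, for the aggregation rule itself
        assert np.std(vals, ddof=1) == pytest.approx(0.1)

    def test_no_reports_is_usage_error(self):
        with pytest.raises(UsageError):
            aggregate([])
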