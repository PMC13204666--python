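"""Confusion matrix, per-class metrics, macro rows and confidence intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgarr.evaluation import (
    ConfusionMatrix,
    class_metrics,
    confusion,
    evaluate,
    macro_ci,
    overall_accuracy,
    proportion_ci,
    round_half_up,
)
from ppgarr.exceptions import InvalidInputError


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 3, 4, 5, 5])
        cm = confusion(y, y)
        assert np.array_equal(cm.counts, np.diag([1, 1, 1, 1, 1, 2]))

    def test_toy_counts(self):
        cm = confusion([0, 1, 1], [0, 1, 0])
        assert cm.counts[1][0] == 1
        assert cm.trace == 2

    def test_matches_sklearn_on_random_vectors(self, rng):
        from sklearn.metrics import confusion_matrix

        y_true = rng.integers(0, 6, 500)
        y_pred = rng.integers(0, 6, 500)
        cm = confusion(y_true, y_pred)
        expected = confusion_matrix(y_true, y_pred, labels=range(6))
        assert np.array_equal(cm.counts, expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion([0, 1], [0])
        with pytest.raises(InvalidInputError):
            confusion([0, 6], [0, 0])

    def test_one_vs_rest_conservation(self, rng):
        cm = confusion(rng.integers(0, 6, 300), rng.integers(0, 6, 300))
        for i in range(6):
            tp, fp, tn, fn = cm.one_vs_rest(i)
            assert tp + fp + tn + fn == cm.total
        assert sum(cm.one_vs_rest(i)[0] for i in range(6)) == cm.trace


class TestClassMetrics:
    def sr_like_matrix(self):
        """SR row mirrors the reported 2887 correct of 2921 true SR samples."""
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 0] = 2887
        counts[0, 1] = 2921 - 2887
        counts[1, 1] = 500
        counts[1, 0] = 80  # some false positives into SR
        return ConfusionMatrix(counts)

    def test_sr_sensitivity_from_reported_counts(self):
        m = class_metrics(self.sr_like_matrix(), 0)
        assert round_half_up(m.sensitivity) == 98.8

    def test_af_sensitivity_from_reported_counts(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[5, 5] = 3143
        counts[5, 0] = 3234 - 3143
        m = class_metrics(ConfusionMatrix(counts), 5)
        assert round_half_up(m.sensitivity) == 97.2

    def test_f1_is_harmonic_mean_of_reported_precision_sensitivity(self):
        p, s = 97.3, 98.8
        f1 = 2 * p * s / (p + s)
        assert round_half_up(f1) == 98.0

    def test_zero_denominator_is_undefined_not_zero(self):
        counts = np.zeros((6, 6), dtype=int)
        counts[0, 0] = 10  # class 3 never occurs nor is predicted
        m = class_metrics(ConfusionMatrix(counts), 3)
        assert m.sensitivity is None and m.precision is None
        assert m.f1 is None
        assert m.specificity is not None  # negatives exist

    def test_specificity_equals_binarized_two_class_matrix(self, rng):
        y_true = rng.integers(0, 6, 400)
        y_pred = rng.integers(0, 6, 400)
        cm = confusion(y_true, y_pred)
        for i in range(6):
            m = class_metrics(cm, i)
            # binarize i-vs-rest and recompute on the 2x2 matrix
            bt = (y_true == i).astype(int)
            bp = (y_pred == i).astype(int)
            tn = np.sum((bt == 0) & (bp == 0))
            fp = np.sum((bt == 0) & (bp == 1))
            expected = tn / (tn + fp) * 100
            assert abs(m.specificity - expected) < 1e-9

    def test_f1_between_min_and_max_of_precision_sensitivity(self, rng):
        cm = confusion(rng.integers(0, 6, 400), rng.integers(0, 6, 400))
        for i in range(6):
            m = class_metrics(cm, i)
            if m.f1 is not None:
                assert (min(m.precision, m.sensitivity) - 1e-9 <= m.f1
                        <= max(m.precision, m.sensitivity) + 1e-9)


class TestOverallAccuracy:
    def test_diagonal_is_100(self):
        acc, _ = overall_accuracy(ConfusionMatrix(np.diag([5] * 6)))
        assert acc == 100.0

    def test_uniform_matrix(self):
        acc, _ = overall_accuracy(ConfusionMatrix(np.ones((6, 6), dtype=int)))
        assert round_half_up(acc) == 16.7

    def test_matches_elementwise_oracle(self, rng):
        counts = rng.integers(0, 50, (6, 6))
        cm = ConfusionMatrix(counts)
        acc, _ = overall_accuracy(cm)
        expected = sum(counts[i][i] for i in range(6)) / counts.sum() * 100
        assert abs(acc - expected) < 1e-12

    def test_invariant_under_relabeling(self, rng):
        counts = rng.integers(0, 50, (6, 6))
        perm = rng.permutation(6)
        acc1, _ = overall_accuracy(ConfusionMatrix(counts))
        acc2, _ = overall_accuracy(ConfusionMatrix(counts[np.ix_(perm, perm)]))
        assert abs(acc1 - acc2) < 1e-12

    def test_empty_matrix_rejected(self):
        with pytest.raises(InvalidInputError):
            overall_accuracy(ConfusionMatrix(np.zeros((6, 6), dtype=int)))


class TestConfidenceIntervals:
    def test_wald_reproduces_sr_sensitivity_interval(self):
        lo, hi = proportion_ci(2887 / 2921, 2921)
        assert (round_half_up(lo), round_half_up(hi)) == (98.4, 99.2)

    def test_degenerate_proportions(self):
        assert proportion_ci(0.0, 50) == (0.0, 0.0)
        assert proportion_ci(1.0, 50) == (100.0, 100.0)

    def test_half_width_hand_computed(self):
        lo, hi = proportion_ci(0.5, 100)
        assert (round_half_up(lo), round_half_up(hi)) == (40.2, 59.8)

    def test_macro_reproduces_reported_sensitivity_row(self):
        sens = [98.8, 69.3, 55.2, 65.1, 85.1, 97.2]
        mean, (lo, hi) = macro_ci(sens)
        assert round_half_up(mean) == 78.5
        assert (round_half_up(lo), round_half_up(hi)) == (64.1, 92.8)

    def test_macro_of_f1_row(self):
        mean, _ = macro_ci([98.0, 74.0, 63.0, 69.8, 85.6, 92.6])
        assert round_half_up(mean) == 80.5

    def test_identical_values_zero_width(self):
        mean, (lo, hi) = macro_ci([70.0] * 6)
        assert mean == lo == hi == 70.0

    def test_single_value_has_undefined_ci(self):
        mean, ci = macro_ci([55.0])
        assert mean == 55.0 and ci is None

    @settings(deadline=None, max_examples=50)
    @given(st.floats(0, 1), st.integers(1, 100000))
    def test_interval_brackets_point_and_stays_in_range(self, p, n):
        lo, hi = proportion_ci(p, n)
        assert 0 <= lo <= p * 100 + 1e-9
        assert p * 100 - 1e-9 <= hi <= 100


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (78.45, 78.5), (78.44999999999999, 78.5), (98.836, 98.8),
        (16.666, 16.7), (0.05, 0.1), (-0.05, -0.1), (97.25, 97.3),
    ])
    def test_half_up_at_one_decimal(self, x, expected):
        assert round_half_up(x) == expected


class TestReport:
    def test_report_structure_and_markdown(self, rng):
        y_true = rng.integers(0, 6, 600)
        y_pred = np.where(rng.random(600) < 0.7, y_true, rng.integers(0, 6, 600))
        report = evaluate(y_true, y_pred)
        assert set(report.per_class) == {"SR", "PVC", "PAC", "VT", "SVT", "AF"}
        md = report.to_markdown()
        assert "| Mean |" in md and "Overall accuracy" in md
        d = report.to_dict()
        assert d["accuracy"]["value"] == report.accuracy
        assert len(d["confusion_matrix"]) == 6

    def test_macro_is_unweighted_mean(self, rng):
        y_true = rng.integers(0, 6, 600)
        y_pred = rng.integers(0, 6, 600)
        report = evaluate(y_true, y_pred)
        sens = [m.sensitivity for m in report.per_class.values()]
        assert abs(report.macro["sensitivity"][0] - np.mean(sens)) < 1e-9

    def test_degenerate_predictions_yield_undefined_macro_not_error(self):
        """All-one-class predictions leave precision/F1 undefined for the
        other classes; the report must mark the rows undefined, not crash."""
        y_true = np.arange(6)
        y_pred = np.zeros(6, dtype=int)
        report = evaluate(y_true, y_pred)
        assert report.per_class["PVC"].precision is None
        mean, ci = report.macro["sensitivity"]
        assert mean is not None  # sensitivity defined for every true class
        assert "—" not in ("",) and "| Mean |" in report.to_markdown()

    def test_confusion_csv(self, tmp_path, rng):
        report = evaluate(rng.integers(0, 6, 100), rng.integers(0, 6, 100))
        path = tmp_path / "cm.csv"
        report.confusion_matrix.to_csv(path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 7 and lines[0].startswith(",pred_SR")
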