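"""Metrics: confusion matrix, one-vs-rest per-class metrics vs an
independent per-sample counting oracle, macro averages, run deltas."""

import numpy as np
import pytest

from skelseq.evaluation import METRICS, compare_runs, confusion, per_class_metrics


def oracle_metrics(y_true, y_pred, n_classes):
    """Independent one-vs-rest oracle: counts TP/FP/FN/TN per class by
    looping over samples, never touching the confusion matrix."""
    out = {}
    N = len(y_true)
    for c in range(1, n_classes + 1):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        tn = N - tp - fp - fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        out[c] = {
            "accuracy": 100 * (tp + tn) / N,
            "precision": 100 * prec,
            "recall": 100 * rec,
            "specificity": 100 * tn / (tn + fp) if tn + fp else 0.0,
            "f1": 100 * 2 * prec * rec / (prec + rec) if prec + rec else 0.0,
            "support": tp + fn,
        }
    return out


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = np.array([1, 2, 3, 3, 12])
        cm = confusion(y, y)
        assert cm.sum() == np.trace(cm) == 5

    def test_small_example(self):
        cm = confusion([1, 1, 2], [1, 2, 2], n_classes=2)
        np.testing.assert_array_equal(cm, [[1, 1], [0, 1]])

    def test_total_conserved_on_random_labels(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(1, 13, 1000)
        y_pred = rng.integers(1, 13, 1000)
        assert confusion(y_true, y_pred).sum() == 1000

    def test_out_of_range_label_reports_index(self):
        with pytest.raises(ValueError, match=r"y_pred\[2\]"):
            confusion([1, 1, 1], [1, 1, 13])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 2], [1])


class TestPerClassMetrics:
    def test_identity_matrix_all_100(self):
        report = per_class_metrics(np.eye(4, dtype=int) * 5)
        per_class = report.table.drop(index="macro")
        assert (per_class[list(METRICS)] == 100.0).all().all()

    def test_two_class_hand_computed(self):
        """[[8,2],[1,9]]: class-1 precision 8/9, recall 8/10, specificity
        9/10, accuracy 17/20, F1 = 2PR/(P+R)."""
        report = per_class_metrics(np.array([[8, 2], [1, 9]]))
        row = report.table.loc[1]
        assert row["precision"] == pytest.approx(88.888888, abs=1e-4)
        assert row["recall"] == pytest.approx(80.0)
        assert row["specificity"] == pytest.approx(90.0)
        assert row["accuracy"] == pytest.approx(85.0)
        assert row["f1"] == pytest.approx(84.210526, abs=1e-4)
        assert row["support"] == 10

    def test_zero_support_class_flagged_and_zero(self):
        cm = np.array([[5, 0], [0, 0]])
        report = per_class_metrics(cm)
        assert report.table.loc[2, "recall"] == 0.0
        assert (2, "recall") in report.undefined

    def test_matches_oracle_on_random_matrices(self):
        """100 random small problems against the per-sample oracle."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            C = int(rng.integers(2, 8))
            n = int(rng.integers(5, 60))
            y_true = rng.integers(1, C + 1, n)
            y_pred = rng.integers(1, C + 1, n)
            report = per_class_metrics(confusion(y_true, y_pred, n_classes=C))
            expected = oracle_metrics(y_true, y_pred, C)
            for c in range(1, C + 1):
                for metric, value in expected[c].items():
                    assert report.table.loc[c, metric] == pytest.approx(value, abs=1e-9), (
                        f"class {c} {metric}"
                    )

    def test_macro_is_unweighted_mean(self):
        rng = np.random.default_rng(1)
        cm = rng.integers(0, 30, size=(12, 12))
        report = per_class_metrics(cm)
        per_class = report.table.drop(index="macro")
        for m in METRICS:
            assert report.macro[m] == pytest.approx(per_class[m].mean(), abs=1e-9)
        assert report.macro["support"] == per_class["support"].sum() == cm.sum()

    def test_micro_accuracy_equals_trace_over_total(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(1, 13, 500)
        y_pred = rng.integers(1, 13, 500)
        cm = confusion(y_true, y_pred)
        assert np.trace(cm) / cm.sum() == (y_true == y_pred).mean()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        cm = rng.integers(0, 20, size=(5, 5))
        perm = rng.permutation(5)
        base = per_class_metrics(cm).table
        permuted = per_class_metrics(cm[np.ix_(perm, perm)]).table
        for new_pos, old_class in enumerate(perm, start=1):
            for m in METRICS:
                assert permuted.loc[new_pos, m] == pytest.approx(
                    base.loc[old_class + 1, m], abs=1e-9
                )


class TestCompareRuns:
    def test_self_comparison_all_zero(self):
        cm = np.diag([5, 8, 3])
        report = per_class_metrics(cm)
        delta = compare_runs(report, report)
        assert (delta["delta"] == 0).all()

    def test_macro_accuracy_delta(self):
        """Two runs whose macro accuracies differ by a known amount."""
        a = per_class_metrics(np.array([[90, 10], [10, 90]]))
        b = per_class_metrics(np.array([[95, 5], [5, 95]]))
        delta = compare_runs(a, b)
        expected = b.macro["accuracy"] - a.macro["accuracy"]
        assert delta.loc["macro_accuracy", "delta"] == pytest.approx(expected)
        assert expected > 0

    def test_class_mismatch_rejected(self):
        a = per_class_metrics(np.eye(3, dtype=int))
        b = per_class_metrics(np.eye(4, dtype=int))
        with pytest.raises(ValueError, match="class"):
            compare_runs(a, b)
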