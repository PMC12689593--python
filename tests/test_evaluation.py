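"""Evaluation metrics from counts, checked against scikit-learn."""

import numpy as np
import pytest

from quanvkd import evaluation as ev


class TestSplits:
    def test_sizes_disjointness_and_coverage(self):
        labels = np.repeat([0, 1, 2, 3], 25)
        protocol = ev.SplitProtocol(test_fraction=0.2, n_repeats=3, base_seed=1)
        for train, test in ev.make_splits(labels, protocol):
            assert len(test) == 20
            assert len(np.intersect1d(train, test)) == 0
            assert len(np.union1d(train, test)) == 100

    def test_stratification_preserves_proportions(self):
        labels = np.repeat([0, 1, 2, 3], [10, 20, 30, 40])
        protocol = ev.SplitProtocol(test_fraction=0.2, n_repeats=2, base_seed=0)
        for _, test in ev.make_splits(labels, protocol):
            counts = np.bincount(labels[test], minlength=4)
            assert counts.tolist() == [2, 4, 6, 8]

    def test_same_seed_gives_identical_splits(self):
        labels = np.repeat([0, 1], 50)
        protocol = ev.SplitProtocol(n_repeats=2, base_seed=9)
        a = ev.make_splits(labels, protocol)
        b = ev.make_splits(labels, protocol)
        for (ta, sa), (tb, sb) in zip(a, b):
            assert np.array_equal(ta, tb) and np.array_equal(sa, sb)

    def test_repeats_differ_from_each_other(self):
        labels = np.repeat([0, 1], 50)
        splits = ev.make_splits(labels, ev.SplitProtocol(n_repeats=2, base_seed=3))
        assert not np.array_equal(splits[0][1], splits[1][1])

    def test_rejects_singleton_class_under_stratification(self):
        labels = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError):
            ev.make_splits(labels, ev.SplitProtocol(n_repeats=1))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 2, 2])
        cm = ev.confusion_matrix(y, y, 3)
        assert np.array_equal(cm, np.diag([1, 1, 2]))

    def test_hand_counted_example(self):
        cm = ev.confusion_matrix([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert np.array_equal(cm, [[1, 1], [0, 2]])

    def test_entries_sum_to_n(self, rng):
        y_true = rng.integers(0, 4, size=50)
        y_pred = rng.integers(0, 4, size=50)
        assert ev.confusion_matrix(y_true, y_pred, 4).sum() == 50

    def test_rejects_out_of_range_labels(self):
        with pytest.raises(ValueError):
            ev.confusion_matrix([0, 5], [0, 1], 3)


class TestClassificationReport:
    def test_identity_confusion_gives_perfect_metrics(self):
        rep = ev.classification_report(np.diag([3, 4, 5]))
        assert np.allclose(rep["precision"], 1.0)
        assert np.allclose(rep["recall"], 1.0)
        assert np.allclose(rep["f1"], 1.0)
        assert rep["accuracy"] == 1.0

    def test_hand_evaluated_two_class_example(self):
        rep = ev.classification_report(np.array([[1, 1], [0, 2]]))
        assert rep["precision"] == pytest.approx([1.0, 2 / 3])
        assert rep["recall"] == pytest.approx([0.5, 1.0])
        assert rep["f1"] == pytest.approx([2 / 3, 0.8])
        assert rep["accuracy"] == pytest.approx(0.75)

    def test_weighted_recall_equals_accuracy(self, rng):
        for _ in range(100):
            cm = rng.integers(0, 20, size=(4, 4))
            cm[0, 0] += 1  # ensure nonempty
            rep = ev.classification_report(cm)
            assert rep["weighted_avg"][1] == pytest.approx(rep["accuracy"],
                                                           abs=1e-12)

    def test_zero_denominator_warns_and_reports_zero(self):
        cm = np.array([[2, 0], [1, 0]])  # class 1 never predicted, never right
        with pytest.warns(UserWarning):
            rep = ev.classification_report(cm)
        assert rep["precision"][1] == 0.0


class TestAUC:
    def test_perfect_separation_is_one(self):
        y = np.array([0, 0, 1, 1])
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        assert ev.roc_auc_ovr(y, probs, 1) == 1.0

    def test_anti_ordered_scores_are_zero(self):
        y = np.array([0, 0, 1, 1])
        probs = np.array([[0.1, 0.9], [0.2, 0.8], [0.9, 0.1], [0.8, 0.2]])
        assert ev.roc_auc_ovr(y, probs, 1) == 0.0

    def test_all_tied_scores_give_half(self):
        y = np.array([0, 1, 0, 1])
        probs = np.full((4, 2), 0.5)
        assert ev.roc_auc_ovr(y, probs, 1) == 0.5

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        scores = rng.uniform(size=30)
        probs = np.stack([1 - scores, scores], axis=1)
        warped = np.stack([1 - scores, np.exp(3 * scores)], axis=1)
        assert ev.roc_auc_ovr(y, probs, 1) == \
            pytest.approx(ev.roc_auc_ovr(y, warped, 1), abs=1e-12)

    def test_degenerate_class_rejected(self):
        y = np.zeros(5, dtype=int)
        probs = np.ones((5, 2)) * 0.5
        with pytest.raises(ValueError):
            ev.roc_auc_ovr(y, probs, 1)


class TestAgainstSklearn:
    """All metrics must match the independent reference within 1e-10."""

    def test_prf_and_auc_on_random_sets(self, rng):
        from sklearn.metrics import (confusion_matrix as sk_cm,
                                     precision_recall_fscore_support,
                                     roc_auc_score)

        for trial in range(100):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(20, 60))
            y_true = rng.integers(0, k, size=n)
            y_true[:k] = np.arange(k)  # every class present
            probs = rng.dirichlet(np.ones(k), size=n)
            y_pred = probs.argmax(axis=1)

            cm = ev.confusion_matrix(y_true, y_pred, k)
            assert np.array_equal(cm, sk_cm(y_true, y_pred, labels=range(k)))

            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = ev.classification_report(cm)
                p, r, f, _ = precision_recall_fscore_support(
                    y_true, y_pred, labels=range(k), zero_division=0)
                np.testing.assert_allclose(rep["precision"], p, atol=1e-10)
                np.testing.assert_allclose(rep["recall"], r, atol=1e-10)
                np.testing.assert_allclose(rep["f1"], f, atol=1e-10)
                for class_k in range(k):
                    got = ev.roc_auc_ovr(y_true, probs, class_k)
                    want = roc_auc_score((y_true == class_k).astype(int),
                                         probs[:, class_k])
                    assert got == pytest.approx(want, abs=1e-10)


class TestAggregate:
    def _report(self, accuracy):
        return ev.EvalReport(
            confusion=np.diag([2, 2]),
            per_class={"precision": np.array([1.0, accuracy]),
                       "recall": np.array([accuracy, 1.0]),
                       "f1": np.array([accuracy, accuracy]),
                       "support": np.array([2, 2])},
            accuracy=accuracy, macro_avg=(accuracy,) * 3,
            weighted_avg=(accuracy,) * 3,
            auc_per_class=np.array([accuracy, accuracy]))

    def test_single_repeat_mean_is_itself_sd_zero(self):
        summary = ev.aggregate_repeats([self._report(0.9)])
        assert summary["accuracy"] == {"mean": 0.9, "sd": 0.0}

    def test_two_repeat_mean(self):
        summary = ev.aggregate_repeats([self._report(0.9), self._report(1.0)])
        assert summary["accuracy"]["mean"] == pytest.approx(0.95)

    def test_sd_invariant_to_ordering(self):
        a = ev.aggregate_repeats([self._report(0.7), self._report(0.9),
                                  self._report(0.8)])
        b = ev.aggregate_repeats([self._report(0.9), self._report(0.8),
                                  self._report(0.7)])
        assert a["accuracy"]["sd"] == pytest.approx(b["accuracy"]["sd"])

    def test_inconsistent_class_counts_rejected(self):
        bad = self._report(0.9)
        bad.confusion = np.diag([1, 1, 1])
        with pytest.raises(ValueError):
            ev.aggregate_repeats([self._report(0.9), bad])


class TestWriters:
    def test_report_files_written(self, tmp_path, rng):
        y_true = np.repeat([0, 1], 10)
        probs = rng.dirichlet(np.ones(2), size=20)
        report = ev.evaluate_probs(y_true, probs, 2)
        ev.write_per_class_csv(report, ["a", "b"], tmp_path / "pc.csv")
        ev.write_summary_csv(ev.aggregate_repeats([report]), "phantom",
                             tmp_path / "sum.csv")
        ev.write_confusion_json(report, ["a", "b"], tmp_path / "cm.json")
        ev.write_roc_points_csv(y_true, probs, 0, tmp_path / "roc.csv")
        import pandas as pd

        pc = pd.read_csv(tmp_path / "pc.csv")
        assert list(pc.columns) == ["class", "P", "R", "FS"]
        summary = pd.read_csv(tmp_path / "sum.csv")
        assert summary["row"].tolist() == ["macro", "weighted"]
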