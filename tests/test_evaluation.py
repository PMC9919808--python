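"""Confusion metrics, the hold-out protocol and the CV comparison harness."""

import numpy as np
import pandas as pd
import pytest
from sklearn.dummy import DummyClassifier

from harcascade import (
    ClassifierSpec,
    accuracy,
    confusion,
    evaluate_split,
    kfold_compare,
    metrics_report,
    precision_recall_f1,
)
from harcascade.errors import (
    InvalidConfigError,
    InvalidInputError,
    StratificationError,
)
from harcascade.evaluation import ConfusionMatrix, render_report, round2

LABELS = ["cough", "fall", "sit", "walk", "sleep"]


def brute_force_metrics(truths, preds, label):
    """Independent oracle: count label pairs directly, no matrix."""
    tp = sum(1 for t, p in zip(truths, preds) if t == label and p == label)
    fp = sum(1 for t, p in zip(truths, preds) if t != label and p == label)
    fn = sum(1 for t, p in zip(truths, preds) if t == label and p != label)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


class TestConfusion:
    def test_hand_counted_example(self):
        cm = confusion(["sit", "sit", "fall"], ["sit", "fall", "fall"])
        df = cm.to_frame()
        assert df.loc["sit", "sit"] == 1
        assert df.loc["sit", "fall"] == 1
        assert df.loc["fall", "fall"] == 1
        assert cm.total == 3

    def test_perfect_predictions_are_diagonal(self):
        y = LABELS * 3
        cm = confusion(y, y)
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion(["sit"], ["sit", "walk"])

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidInputError):
            confusion(["sit"], ["jump"], class_order=["sit", "walk"])


class TestPerClassMetrics:
    def test_hand_evaluated_fractions(self):
        # class with TP=2, FP=1, FN=3
        cm = ConfusionMatrix(np.array([[2, 3], [1, 4]]), ("a", "b"))
        p, r, f1 = precision_recall_f1(cm, "a")
        assert p == pytest.approx(2 / 3)
        assert r == pytest.approx(2 / 5)
        assert f1 == pytest.approx(1 / 2)

    def test_perfect_classifier_scores_one(self):
        cm = confusion(LABELS, LABELS)
        for lab in LABELS:
            assert precision_recall_f1(cm, lab) == (1.0, 1.0, 1.0)

    def test_zero_denominators_give_zero(self):
        # class "b" never predicted and never true-positive
        cm = ConfusionMatrix(np.array([[2, 0], [3, 0]]), ("a", "b"))
        p, r, f1 = precision_recall_f1(cm, "b")
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_f1_from_published_precision_recall_pair(self):
        # 0.88 precision with perfect recall balances to 0.94
        f1 = 2 * 0.88 * 1.00 / (0.88 + 1.00)
        assert round2(f1) == 0.94

    def test_accuracy_trace_over_total(self):
        cm = confusion(["sit", "sit", "fall"], ["sit", "fall", "fall"])
        assert accuracy(cm) == pytest.approx(2 / 3)
        assert accuracy(confusion(LABELS, LABELS)) == 1.0
        assert accuracy(confusion(["sit", "sit"], ["walk", "walk"])) == 0.0

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(np.zeros((2, 2), dtype=int), ("a", "b"))
        with pytest.raises(InvalidInputError):
            accuracy(cm)

    def test_micro_average_identity_on_random_matrices(self, rng):
        # micro precision == micro recall == accuracy, algebraically
        for _ in range(50):
            k = rng.integers(2, 6)
            counts = rng.integers(0, 20, (k, k))
            counts[0, 0] += 1  # non-empty
            order = tuple(f"c{i}" for i in range(k))
            cm = ConfusionMatrix(counts, order)
            tps, fps, fns = zip(*(cm.tp_fp_fn(c) for c in order))
            micro_p = sum(tps) / (sum(tps) + sum(fps))
            micro_r = sum(tps) / (sum(tps) + sum(fns))
            assert micro_p == pytest.approx(micro_r)
            assert micro_p == pytest.approx(accuracy(cm))

    def test_agrees_with_brute_force_counter(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 60))
            truths = rng.choice(LABELS, n)
            preds = rng.choice(LABELS, n)
            cm = confusion(truths, preds, class_order=LABELS)
            for lab in LABELS:
                expected = brute_force_metrics(truths, preds, lab)
                assert precision_recall_f1(cm, lab) == pytest.approx(expected)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected", [(0.945, 0.95), (0.944, 0.94), (0.715, 0.72), (0.7149, 0.71)]
    )
    def test_half_up_two_decimals(self, value, expected):
        assert round2(value) == expected


class TestEvaluateSplit:
    def test_report_layout_and_counts(self, separable_table):
        report = evaluate_split(separable_table, mode="ptle", seed=3)
        n = len(separable_table)
        assert report.total_support == round(0.3 * n)
        assert set(report.per_class) == set(separable_table["label"].unique())
        text = render_report(report)
        for col in ("Precision", "Recall", "F1-Score", "Support"):
            assert col in text

    def test_balanced_split_is_stratified(self):
        rng = np.random.default_rng(0)
        from harcascade.features import FEATURE_COLUMNS

        df = pd.DataFrame(
            rng.normal(0, 1, (1000, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS
        )
        df["label"] = np.repeat(LABELS, 200)
        report = evaluate_split(df, mode="flat", specs=ClassifierSpec("CART"), seed=0)
        assert report.total_support == 300
        assert all(m.support == 60 for m in report.per_class.values())

    def test_invariant_to_row_shuffling(self, separable_table):
        shuffled = separable_table.sample(frac=1.0, random_state=99)
        a = evaluate_split(separable_table, mode="flat", seed=5)
        b = evaluate_split(shuffled, mode="flat", seed=5)
        assert a.overall_accuracy == b.overall_accuracy
        assert a.to_dict() == b.to_dict()

    def test_tiny_class_raises_stratification_error(self, separable_table):
        df = separable_table.copy()
        df = pd.concat([df[df["label"] != "fall"], df[df["label"] == "fall"].head(1)])
        with pytest.raises(StratificationError):
            evaluate_split(df, mode="flat", seed=0)

    def test_bad_fraction_rejected(self, separable_table):
        with pytest.raises(InvalidConfigError):
            evaluate_split(separable_table, test_fraction=1.5)


class TestKFoldCompare:
    def test_constant_baseline_scores_majority_proportion(self, separable_table):
        baseline = DummyClassifier(strategy="most_frequent")
        balanced = separable_table.groupby("label", group_keys=False).head(40)
        result = kfold_compare(
            balanced, algorithms=[], k=5, seed=0, extra_estimators={"CONST": baseline}
        )
        assert result.per_algorithm["CONST"].mean == pytest.approx(0.2, abs=0.02)

    def test_mean_std_agree_with_fold_scores(self, separable_table):
        small = separable_table.groupby("label", group_keys=False).head(40)
        result = kfold_compare(
            small, algorithms=[ClassifierSpec("CART"), ClassifierSpec("NB")], k=4, seed=1
        )
        for score in result.per_algorithm.values():
            arr = np.array(score.fold_scores)
            assert score.mean == pytest.approx(arr.mean())
            assert score.std == pytest.approx(arr.std())
            assert len(arr) == 4

    def test_class_smaller_than_k_rejected(self, separable_table):
        df = separable_table.groupby("label", group_keys=False).head(5)
        with pytest.raises(InvalidConfigError):
            kfold_compare(df, k=10, seed=0)

    def test_folds_shared_across_algorithms(self, separable_table):
        small = separable_table.groupby("label", group_keys=False).head(40)
        a = kfold_compare(small, algorithms=[ClassifierSpec("CART", seed=0)], k=4, seed=2)
        b = kfold_compare(
            small,
            algorithms=[ClassifierSpec("CART", seed=0), ClassifierSpec("NB")],
            k=4,
            seed=2,
        )
        assert a.per_algorithm["CART"].fold_scores == b.per_algorithm["CART"].fold_scores
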