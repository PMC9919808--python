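"""Confusion-matrix metrics, the hold-out protocol, and algorithm comparison.

Per-class metrics follow the usual one-vs-rest counts on the confusion
matrix: for class A, TP is the diagonal entry, FP the rest of A's column,
FN the rest of A's row; then

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)
    accuracy  = trace / total

A metric whose denominator is zero is defined as 0 — the conservative
convention.  Values are kept at full precision internally; rendered tables
round to two decimals, half-up.

The hold-out protocol trains on ~70% of the rows and reports on the
remaining ~30%, stratified by leaf label.  Algorithm comparison uses
stratified k-fold cross-validation (fold accuracy as the score), with the
same fold assignment shared across algorithms for a paired comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold, train_test_split

from .cascade import (
    ALGORITHMS,
    ClassifierSpec,
    make_estimator,
    predict_labels,
    train_flat,
    train_ptle,
)
from .errors import InvalidConfigError, InvalidInputError, StratificationError
from .features import FEATURE_COLUMNS
from .taxonomy import Taxonomy, DEFAULT_TAXONOMY

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "CVResult",
    "confusion",
    "precision_recall_f1",
    "accuracy",
    "metrics_report",
    "evaluate_split",
    "kfold_compare",
    "round2",
    "render_report",
    "render_cv_table",
]


def round2(x: float) -> float:
    """Round to 2 decimals, half-up (0.945 -> 0.95), for display only."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count table indexed by (true label, predicted label)."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.class_order):
            raise InvalidInputError("counts must be square and match class_order")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index(self, label: str) -> int:
        try:
            return self.class_order.index(label)
        except ValueError:
            raise InvalidInputError(f"label {label!r} not in class order") from None

    def tp_fp_fn(self, label: str) -> tuple[int, int, int]:
        i = self.index(label)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum()) - tp
        fn = int(self.counts[i, :].sum()) - tp
        return tp, fp, fn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order, columns=self.class_order)


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Count table with rows = true class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if len(t) != len(p):
        raise InvalidInputError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    if class_order is None:
        class_order = sorted(set(t) | set(p))
    order = tuple(class_order)
    idx = {c: i for i, c in enumerate(order)}
    unknown = (set(t) | set(p)) - set(order)
    if unknown:
        raise InvalidInputError(f"labels outside the class set: {sorted(map(str, unknown))}")
    counts = np.zeros((len(order), len(order)), dtype=int)
    for ti, pi in zip(t, p):
        counts[idx[ti], idx[pi]] += 1
    return ConfusionMatrix(counts, order)


def precision_recall_f1(cm: ConfusionMatrix, label: str) -> tuple[float, float, float]:
    """Per-class precision, recall and F1; zero-denominator cases give 0."""
    tp, fp, fn = cm.tp_fp_fn(label)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions: trace over total."""
    total = cm.total
    if total == 0:
        raise InvalidInputError("accuracy undefined for an empty confusion matrix")
    return float(np.trace(cm.counts)) / total


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class MetricsReport:
    per_class: Mapping[str, ClassMetrics]
    overall_accuracy: float
    confusion: ConfusionMatrix

    @property
    def total_support(self) -> int:
        return sum(m.support for m in self.per_class.values())

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "support": m.support,
                }
                for c, m in self.per_class.items()
            },
            "overall_accuracy": self.overall_accuracy,
            "class_order": list(self.confusion.class_order),
            "confusion": self.confusion.counts.tolist(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def metrics_report(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str] | None = None,
) -> MetricsReport:
    cm = confusion(true_labels, predicted_labels, class_order)
    per_class = {}
    for i, c in enumerate(cm.class_order):
        p, r, f1 = precision_recall_f1(cm, c)
        per_class[c] = ClassMetrics(p, r, f1, int(cm.counts[i, :].sum()))
    return MetricsReport(per_class, accuracy(cm), cm)


def render_report(report: MetricsReport) -> str:
    """Aligned-text metrics table (2-decimal display rounding)."""
    lines = [f"{'Activity':<10}{'Precision':>10}{'Recall':>10}{'F1-Score':>10}{'Support':>10}"]
    for c, m in report.per_class.items():
        lines.append(
            f"{c:<10}{round2(m.precision):>10.2f}{round2(m.recall):>10.2f}"
            f"{round2(m.f1):>10.2f}{m.support:>10d}"
        )
    lines.append(f"Total samples: {report.total_support}")
    lines.append(f"Overall accuracy: {round2(report.overall_accuracy):.2f}")
    return "\n".join(lines)


def _sorted_canonical(features: pd.DataFrame) -> pd.DataFrame:
    # content-deterministic row order, so the seeded split does not depend
    # on how the caller happened to shuffle the table
    cols = ["label", *FEATURE_COLUMNS]
    return features.sort_values(cols, kind="mergesort").reset_index(drop=True)


def evaluate_split(
    features: pd.DataFrame,
    mode: str = "ptle",
    specs=None,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> MetricsReport:
    """Stratified hold-out evaluation: fit on ~(1 - test_fraction), report
    per-class metrics and overall accuracy on the rest.

    The split permutation is derived from ``seed`` on a canonical row
    ordering, so shuffling the input rows does not change the result.
    """
    if not 0.0 < test_fraction < 1.0:
        raise InvalidConfigError("test_fraction must be in (0, 1)")
    if mode not in ("ptle", "flat"):
        raise InvalidConfigError(f"unknown mode {mode!r}")
    df = _sorted_canonical(features)
    y = df["label"].to_numpy()
    try:
        train_df, test_df = train_test_split(
            df, test_size=test_fraction, stratify=y, random_state=seed
        )
    except ValueError as exc:
        raise StratificationError(str(exc)) from exc
    if set(train_df["label"]) != set(y) or set(test_df["label"]) != set(y):
        raise StratificationError("a class is absent from one side of the split")
    if mode == "ptle":
        model = train_ptle(train_df, specs=specs, taxonomy=taxonomy)
    else:
        model = train_flat(train_df, spec=specs)
    preds = predict_labels(model, test_df)
    return metrics_report(
        test_df["label"].to_numpy(), preds, class_order=sorted(set(y))
    )


@dataclass(frozen=True)
class AlgorithmScore:
    mean: float
    std: float
    fold_scores: tuple[float, ...]


@dataclass(frozen=True)
class CVResult:
    per_algorithm: Mapping[str, AlgorithmScore]
    k: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "per_algorithm": {
                a: {"mean": s.mean, "std": s.std, "fold_scores": list(s.fold_scores)}
                for a, s in self.per_algorithm.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def default_algorithm_suite(seed: int = 0) -> list[ClassifierSpec]:
    """One spec per supported algorithm, in canonical order."""
    return [ClassifierSpec(a, seed=seed) for a in ALGORITHMS]


def kfold_compare(
    features: pd.DataFrame,
    algorithms: Sequence[ClassifierSpec] | None = None,
    k: int = 10,
    seed: int = 0,
    extra_estimators: Mapping[str, object] | None = None,
) -> CVResult:
    """Stratified k-fold comparison of classification algorithms.

    Scores are fold accuracies in [0, 1]; the fold assignment is fixed
    once and reused for every algorithm, so differences are paired.
    ``extra_estimators`` admits additional ready-made scikit-learn
    estimators (e.g. a trivial baseline) under custom names.
    """
    if k < 2:
        raise InvalidConfigError("k must be at least 2")
    if algorithms is None:
        algorithms = default_algorithm_suite(seed)
    if "label" not in features.columns:
        raise InvalidInputError("feature table must carry a 'label' column")
    y = features["label"].to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise InvalidConfigError(
            f"every class needs at least k={k} members; too small: {dict(small)}"
        )
    X = features.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))

    candidates: list[tuple[str, object]] = [(s.algorithm, make_estimator(s)) for s in algorithms]
    for name, est in (extra_estimators or {}).items():
        candidates.append((name, est))

    per_algorithm: dict[str, AlgorithmScore] = {}
    for name, est in candidates:
        scores = []
        for train_idx, val_idx in folds:
            model = clone(est)
            model.fit(X[train_idx], y[train_idx])
            scores.append(float(np.mean(model.predict(X[val_idx]) == y[val_idx])))
        arr = np.array(scores)
        per_algorithm[name] = AlgorithmScore(float(arr.mean()), float(arr.std()), tuple(scores))
    return CVResult(per_algorithm, k, seed)


def render_cv_table(result: CVResult) -> str:
    lines = [f"{'Algorithm':<12}{'Mean Score':>12}{'Std Score':>12}"]
    for name, s in result.per_algorithm.items():
        lines.append(f"{name:<12}{s.mean:>12.3f}{s.std:>12.4f}")
    return "\n".join(lines)
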