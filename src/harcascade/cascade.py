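"""The hierarchical classifier cascade and the flat baseline.

The cascade — often called a parallel-training / logical-execution (PTLE)
scheme — splits five-way activity recognition into three smaller problems:

* **model 1** sees every training row, relabeled to the coarse groups
  (normal vs abnormal);
* **model 2** is trained only on the normal rows (sit / walk / sleep);
* **model 3** is trained only on the abnormal rows (cough / fall).

The three fits share no state, so they can run in parallel; "parallel" is
a logical-independence contract, not a concurrency mandate, and this
implementation fits them sequentially.  At prediction time model 1 routes
each row: abnormal rows get model 3's verdict, normal rows model 2's, so
the output is always a leaf activity.

The flat baseline is a single five-class model trained on all rows — the
conventional approach the cascade is compared against.

Any of seven classical algorithms can back each model (random forest,
k-nearest neighbours, decision tree, support-vector machine, logistic
regression, linear discriminant analysis, Gaussian naive Bayes).  The
default is a random forest with 100 trees, minimum 1 sample per leaf and
minimum 2 samples to split — the configuration that wins the
cross-validated comparison on this task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import joblib
import numpy as np
import pandas as pd
import yaml
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    InvalidConfigError,
    InvalidInputError,
    UntrainableModelError,
)
from .features import FEATURE_COLUMNS
from .taxonomy import ABNORMAL_GROUP, DEFAULT_TAXONOMY, Taxonomy, validate_labels

__all__ = [
    "ALGORITHMS",
    "ClassifierSpec",
    "TrainedCascade",
    "TrainedFlat",
    "make_estimator",
    "build_cascade_datasets",
    "train_ptle",
    "predict_ptle",
    "train_flat",
    "predict_flat",
    "predict_labels",
    "save_model",
    "load_model",
]

ALGORITHMS: tuple[str, ...] = ("RF", "KNN", "CART", "SVM", "LR", "LDA", "NB")

_RF_DEFAULTS = {"n_estimators": 100, "min_samples_leaf": 1, "min_samples_split": 2}


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm choice plus hyperparameters for one model slot."""

    algorithm: str = "RF"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise InvalidConfigError(
                f"unknown algorithm {self.algorithm!r}; choose one of {ALGORITHMS}"
            )


def make_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator a spec describes."""
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "RF":
        params = dict(_RF_DEFAULTS)
        params.update(hp)
        return RandomForestClassifier(random_state=spec.seed, **params)
    if spec.algorithm == "KNN":
        return KNeighborsClassifier(**hp)
    if spec.algorithm == "CART":
        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if spec.algorithm == "SVM":
        return SVC(random_state=spec.seed, **hp)
    if spec.algorithm == "LR":
        hp.setdefault("max_iter", 2000)
        return LogisticRegression(random_state=spec.seed, **hp)
    if spec.algorithm == "LDA":
        return LinearDiscriminantAnalysis(**hp)
    return GaussianNB(**hp)


def _check_feature_frame(features: pd.DataFrame) -> np.ndarray:
    missing = set(FEATURE_COLUMNS) - set(features.columns)
    if missing:
        raise InvalidInputError(f"feature table missing columns: {sorted(missing)}")
    return features.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)


def build_cascade_datasets(
    features: pd.DataFrame, taxonomy: Taxonomy = DEFAULT_TAXONOMY
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition one leaf-labeled feature table into the three sub-datasets.

    Returns ``(d1, d2, d3)``: d1 is every row with labels mapped to the
    coarse groups; d2 keeps the normal-group rows with their leaf labels;
    d3 the abnormal-group rows likewise.  Row counts always satisfy
    ``len(d1) == len(d2) + len(d3)``.
    """
    if "label" not in features.columns:
        raise InvalidInputError("feature table must carry a 'label' column")
    validate_labels(features["label"].unique())
    groups = features["label"].map(taxonomy.group)
    d1 = features.copy()
    d1["label"] = groups
    d2 = features.loc[groups != ABNORMAL_GROUP].copy()
    d3 = features.loc[groups == ABNORMAL_GROUP].copy()
    return d1, d2, d3


@dataclass
class TrainedCascade:
    """Three fitted models plus the routing taxonomy."""

    model1: object
    model2: object
    model3: object
    taxonomy: Taxonomy
    specs: dict[str, ClassifierSpec]
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return predict_ptle(self, features)


@dataclass
class TrainedFlat:
    """A single fitted five-class model."""

    model: object
    spec: ClassifierSpec
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return predict_flat(self, features)


def _normalize_specs(
    specs: ClassifierSpec | Mapping[str, ClassifierSpec] | None,
) -> dict[str, ClassifierSpec]:
    if specs is None:
        specs = ClassifierSpec()
    if isinstance(specs, ClassifierSpec):
        return {"model1": specs, "model2": specs, "model3": specs}
    out = dict(specs)
    missing = {"model1", "model2", "model3"} - set(out)
    if missing:
        raise InvalidConfigError(f"specs missing entries for: {sorted(missing)}")
    return out


def _untrainable_reason(dataset: pd.DataFrame) -> str | None:
    if len(dataset) == 0:
        return "empty training dataset"
    classes = dataset["label"].unique()
    if len(classes) < 2:
        return f"needs at least 2 classes, got {sorted(map(str, classes))}"
    return None


def _fit_one(name: str, dataset: pd.DataFrame, spec: ClassifierSpec):
    reason = _untrainable_reason(dataset)
    if reason is not None:
        raise UntrainableModelError(f"{name}: {reason}")
    X = _check_feature_frame(dataset)
    est = make_estimator(spec)
    est.fit(X, dataset["label"].to_numpy())
    return est


def train_ptle(
    features: pd.DataFrame,
    specs: ClassifierSpec | Mapping[str, ClassifierSpec] | None = None,
    taxonomy: Taxonomy = DEFAULT_TAXONOMY,
) -> TrainedCascade:
    """Fit the three cascade models on one leaf-labeled feature table."""
    spec_map = _normalize_specs(specs)
    d1, d2, d3 = build_cascade_datasets(features, taxonomy)
    problems = [
        f"{name}: {reason}"
        for name, d in (("model1", d1), ("model2", d2), ("model3", d3))
        if (reason := _untrainable_reason(d)) is not None
    ]
    if problems:
        raise UntrainableModelError("; ".join(problems))
    model1 = _fit_one("model1", d1, spec_map["model1"])
    model2 = _fit_one("model2", d2, spec_map["model2"])
    model3 = _fit_one("model3", d3, spec_map["model3"])
    return TrainedCascade(model1, model2, model3, taxonomy, spec_map)


def predict_ptle(cascade: TrainedCascade, features: pd.DataFrame) -> np.ndarray:
    """Route every row through the cascade; output is always a leaf label."""
    X = _check_feature_frame(features)
    n = len(X)
    out = np.empty(n, dtype=object)
    if n == 0:
        return out
    gate = cascade.model1.predict(X)
    abnormal = gate == ABNORMAL_GROUP
    if abnormal.any():
        out[abnormal] = cascade.model3.predict(X[abnormal])
    if (~abnormal).any():
        out[~abnormal] = cascade.model2.predict(X[~abnormal])
    return out


def train_flat(
    features: pd.DataFrame, spec: ClassifierSpec | None = None
) -> TrainedFlat:
    """Fit the single five-class baseline model."""
    if spec is None:
        spec = ClassifierSpec()
    if "label" not in features.columns:
        raise InvalidInputError("feature table must carry a 'label' column")
    validate_labels(features["label"].unique())
    model = _fit_one("flat", features, spec)
    return TrainedFlat(model, spec)


def predict_flat(flat: TrainedFlat, features: pd.DataFrame) -> np.ndarray:
    X = _check_feature_frame(features)
    return np.asarray(flat.model.predict(X), dtype=object)


def predict_labels(model, features: pd.DataFrame) -> np.ndarray:
    """Predict leaf labels with either a cascade, a flat model, or any
    object exposing a scikit-learn style ``predict``."""
    if isinstance(model, TrainedCascade):
        return predict_ptle(model, features)
    if isinstance(model, TrainedFlat):
        return predict_flat(model, features)
    if hasattr(model, "predict"):
        return np.asarray(model.predict(_check_feature_frame(features)), dtype=object)
    raise InvalidInputError(f"cannot predict with object of type {type(model).__name__}")


# ---------------------------------------------------------------------------
# persistence: a directory of serialized models plus a YAML manifest

_FORMAT_VERSION = 1


def _spec_to_dict(spec: ClassifierSpec) -> dict:
    return {
        "algorithm": spec.algorithm,
        "hyperparameters": dict(spec.hyperparameters),
        "seed": spec.seed,
    }


def _spec_from_dict(d: Mapping) -> ClassifierSpec:
    return ClassifierSpec(d["algorithm"], dict(d.get("hyperparameters", {})), d.get("seed", 0))


def save_model(model: TrainedCascade | TrainedFlat, directory) -> Path:
    """Persist a trained cascade or flat model to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(model, TrainedCascade):
        manifest = {
            "format_version": _FORMAT_VERSION,
            "kind": "ptle",
            "feature_columns": list(model.feature_columns),
            "taxonomy": dict(model.taxonomy.group_of),
            "specs": {k: _spec_to_dict(v) for k, v in model.specs.items()},
        }
        for name in ("model1", "model2", "model3"):
            joblib.dump(getattr(model, name), directory / f"{name}.joblib")
    elif isinstance(model, TrainedFlat):
        manifest = {
            "format_version": _FORMAT_VERSION,
            "kind": "flat",
            "feature_columns": list(model.feature_columns),
            "spec": _spec_to_dict(model.spec),
        }
        joblib.dump(model.model, directory / "model.joblib")
    else:
        raise InvalidInputError(f"cannot save object of type {type(model).__name__}")
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return directory


def load_model(directory) -> TrainedCascade | TrainedFlat:
    """Load a model directory written by :func:`save_model`."""
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    if manifest.get("format_version") != _FORMAT_VERSION:
        raise InvalidInputError(f"unsupported model format: {manifest.get('format_version')}")
    cols = tuple(manifest["feature_columns"])
    if manifest["kind"] == "ptle":
        return TrainedCascade(
            model1=joblib.load(directory / "model1.joblib"),
            model2=joblib.load(directory / "model2.joblib"),
            model3=joblib.load(directory / "model3.joblib"),
            taxonomy=Taxonomy(manifest["taxonomy"]),
            specs={k: _spec_from_dict(v) for k, v in manifest["specs"].items()},
            feature_columns=cols,
        )
    if manifest["kind"] == "flat":
        return TrainedFlat(
            model=joblib.load(directory / "model.joblib"),
            spec=_spec_from_dict(manifest["spec"]),
            feature_columns=cols,
        )
    raise InvalidInputError(f"unknown model kind {manifest['kind']!r}")
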