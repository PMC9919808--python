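"""Cascade training, routing logic, flat baseline, persistence."""

import numpy as np
import pandas as pd
import pytest

from harcascade import (
    ALGORITHMS,
    ClassifierSpec,
    DEFAULT_TAXONOMY,
    build_cascade_datasets,
    load_model,
    predict_flat,
    predict_ptle,
    save_model,
    train_flat,
    train_ptle,
)
from harcascade.errors import (
    InvalidConfigError,
    InvalidLabelError,
    UntrainableModelError,
)
from harcascade.features import FEATURE_COLUMNS
from harcascade.taxonomy import ABNORMAL_GROUP, NORMAL_GROUP


def random_features(n, rng, label=None):
    df = pd.DataFrame(rng.normal(0, 1, (n, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS)
    if label is not None:
        df["label"] = label
    return df


class TestCascadeDatasets:
    def test_partition_arithmetic(self, rng):
        df = pd.concat(
            [random_features(10, rng, "sit"), random_features(5, rng, "cough")],
            ignore_index=True,
        )
        d1, d2, d3 = build_cascade_datasets(df)
        assert len(d1) == 15 and len(d2) == 10 and len(d3) == 5
        assert (d1["label"] == NORMAL_GROUP).sum() == 10
        assert (d1["label"] == ABNORMAL_GROUP).sum() == 5

    def test_leaf_label_conservation(self, separable_table):
        d1, d2, d3 = build_cascade_datasets(separable_table)
        assert len(d1) == len(d2) + len(d3)
        combined = pd.concat([d2["label"], d3["label"]]).value_counts()
        original = separable_table["label"].value_counts()
        assert combined.sort_index().equals(original.sort_index())

    def test_normal_only_data_yields_empty_d3(self, rng):
        df = random_features(20, rng, "sit")
        df.loc[10:, "label"] = "walk"
        d1, d2, d3 = build_cascade_datasets(df)
        assert len(d3) == 0
        with pytest.raises(UntrainableModelError, match="model3"):
            train_ptle(df)

    def test_unknown_label_rejected(self, rng):
        df = random_features(5, rng, "jumping")
        with pytest.raises(InvalidLabelError):
            build_cascade_datasets(df)


class TestTraining:
    def test_submodels_perfect_on_separable_training_data(self, separable_table, rf_spec):
        cascade = train_ptle(separable_table, specs=rf_spec)
        d1, d2, d3 = build_cascade_datasets(separable_table)
        for model, d in [(cascade.model1, d1), (cascade.model2, d2), (cascade.model3, d3)]:
            X = d[list(FEATURE_COLUMNS)].to_numpy()
            assert np.mean(model.predict(X) == d["label"].to_numpy()) == 1.0

    def test_flat_perfect_on_separable_training_data(self, separable_table, rf_spec):
        flat = train_flat(separable_table, spec=rf_spec)
        preds = predict_flat(flat, separable_table)
        assert np.mean(preds == separable_table["label"].to_numpy()) == 1.0

    def test_deterministic_given_seed(self, separable_table, rng):
        spec = ClassifierSpec("RF", seed=7)
        probe = random_features(50, rng)
        a = predict_ptle(train_ptle(separable_table, specs=spec), probe)
        b = predict_ptle(train_ptle(separable_table, specs=spec), probe)
        assert np.array_equal(a, b)

    def test_default_spec_is_rf_100_trees(self, separable_table):
        cascade = train_ptle(separable_table)
        for m in (cascade.model1, cascade.model2, cascade.model3):
            assert m.n_estimators == 100
            assert m.min_samples_leaf == 1
            assert m.min_samples_split == 2

    def test_single_class_flat_data_rejected(self, rng):
        with pytest.raises(UntrainableModelError):
            train_flat(random_features(10, rng, "sit"))

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(InvalidConfigError):
            ClassifierSpec("XGB")

    def test_all_algorithms_instantiable(self, separable_table):
        small = separable_table.groupby("label", group_keys=False).head(30)
        for algo in ALGORITHMS:
            cascade = train_ptle(small, specs=ClassifierSpec(algo, seed=0))
            preds = predict_ptle(cascade, small)
            assert len(preds) == len(small)


class TestRouting:
    def test_output_always_leaf_label(self, separable_table, rng):
        cascade = train_ptle(separable_table)
        preds = predict_ptle(cascade, random_features(200, rng))
        assert set(preds) <= {"cough", "fall", "sit", "walk", "sleep"}

    def test_matches_row_by_row_two_stage_lookup(self, separable_table, rng):
        cascade = train_ptle(separable_table)
        probe = random_features(100, rng)
        preds = predict_ptle(cascade, probe)
        X = probe[list(FEATURE_COLUMNS)].to_numpy()
        for i in range(len(probe)):
            group = cascade.model1.predict(X[i : i + 1])[0]
            sub = cascade.model3 if group == ABNORMAL_GROUP else cascade.model2
            assert preds[i] == sub.predict(X[i : i + 1])[0]

    def test_gate_decision_iff_abnormal_output(self, separable_table, rng):
        cascade = train_ptle(separable_table)
        probe = random_features(300, rng)
        preds = predict_ptle(cascade, probe)
        gate = cascade.model1.predict(probe[list(FEATURE_COLUMNS)].to_numpy())
        is_abn_pred = np.isin(preds.astype(str), ["cough", "fall"])
        assert np.array_equal(gate == ABNORMAL_GROUP, is_abn_pred)

    def test_all_normal_gate_confines_outputs(self, separable_table, rng):
        cascade = train_ptle(separable_table)

        class AlwaysNormal:
            def predict(self, X):
                return np.array([NORMAL_GROUP] * len(X), dtype=object)

        cascade.model1 = AlwaysNormal()
        preds = predict_ptle(cascade, random_features(100, rng))
        assert set(preds) <= {"sit", "walk", "sleep"}

    def test_model2_never_affects_abnormal_rows(self, separable_table, rng):
        cascade = train_ptle(separable_table)
        probe = random_features(300, rng)
        before = predict_ptle(cascade, probe)
        abnormal = np.isin(before.astype(str), ["cough", "fall"])

        class ConstantSit:
            def predict(self, X):
                return np.array(["sit"] * len(X), dtype=object)

        cascade.model2 = ConstantSit()
        after = predict_ptle(cascade, probe)
        assert np.array_equal(before[abnormal], after[abnormal])


class TestPersistence:
    @pytest.mark.parametrize("mode", ["ptle", "flat"])
    def test_round_trip_preserves_predictions(self, separable_table, tmp_path, rng, mode):
        if mode == "ptle":
            model = train_ptle(separable_table)
        else:
            model = train_flat(separable_table)
        probe = random_features(80, rng)
        before = model.predict(probe)
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        assert np.array_equal(before, loaded.predict(probe))
        assert (tmp_path / "m" / "manifest.yaml").exists()

    def test_manifest_preserves_taxonomy_and_specs(self, separable_table, tmp_path):
        spec = ClassifierSpec("CART", seed=5)
        save_model(train_ptle(separable_table, specs=spec), tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        assert loaded.taxonomy.group_of == DEFAULT_TAXONOMY.group_of
        assert loaded.specs["model2"].algorithm == "CART"
        assert tuple(loaded.feature_columns) == FEATURE_COLUMNS
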