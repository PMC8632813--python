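import numpy as np
import pandas as pd
import pytest

from fedcohort.errors import (
    CenterMismatchError,
    DegenerateDataError,
    FormatError,
    SchemaConflictError,
)
from fedcohort.preprocessing import (
    apply_imputer,
    apply_scaler,
    compute_class_weights,
    encode_for_trees,
    exclude_patients,
    fit_imputer,
    fit_scaler,
    intersect_variables,
    random_oversample,
    sample_weights,
)
from fedcohort.synthetic_cohort import CohortTable, VariableSpec

from conftest import MIXED_SCHEMA, make_mixed_cohort


def _cohort_from_frame(df, schema, center="A"):
    df = df.copy()
    df.index = pd.Index([f"{center}-{i}" for i in range(len(df))], name="patient_id")
    return CohortTable(data=df, schema=schema, center_id=center)


class TestExclusion:
    def test_fully_observed_cohort_unchanged(self, mixed_cohort):
        out = exclude_patients(mixed_cohort)
        pd.testing.assert_frame_equal(out.data, mixed_cohort.data)

    def test_majority_missing_boundary_is_strict(self):
        schema = tuple(VariableSpec(f"v{i}", "continuous") for i in range(10))
        row_6_missing = {f"v{i}": (np.nan if i < 6 else 1.0) for i in range(10)}
        row_5_missing = {f"v{i}": (np.nan if i < 5 else 1.0) for i in range(10)}
        df = pd.DataFrame([row_6_missing, row_5_missing])
        df["outcome"] = [0, 1]
        out = exclude_patients(_cohort_from_frame(df, schema))
        assert len(out.data) == 1  # exactly-50% row retained, 60% row dropped
        assert out.data["outcome"].iloc[0] == 1

    def test_missing_outcome_and_sparse_rows_dropped(self):
        schema = tuple(VariableSpec(f"v{i}", "continuous") for i in range(5))
        rows = []
        rows.append({**{f"v{i}": 1.0 for i in range(5)}, "outcome": np.nan})
        rows.append({**{f"v{i}": (np.nan if i < 3 else 1.0) for i in range(5)}, "outcome": 0})
        for _ in range(3):
            rows.append({**{f"v{i}": 1.0 for i in range(5)}, "outcome": 1})
        out = exclude_patients(_cohort_from_frame(pd.DataFrame(rows), schema))
        assert len(out.data) == 3


class TestIntersection:
    def test_identity_and_order(self):
        assert intersect_variables(MIXED_SCHEMA, MIXED_SCHEMA) == MIXED_SCHEMA

    def test_default_specs_share_all_variables(self, default_specs):
        a, b = default_specs
        assert len(intersect_variables(a.schema, b.schema)) == 16

    def test_set_semantics(self):
        x = VariableSpec("x", "continuous")
        y = VariableSpec("y", "continuous")
        z = VariableSpec("z", "continuous")
        assert intersect_variables((x, y), (y, z)) == (y,)

    def test_kind_conflict_raises(self):
        a = (VariableSpec("v", "continuous"),)
        b = (VariableSpec("v", "categorical", categories=("p", "q")),)
        with pytest.raises(SchemaConflictError):
            intersect_variables(a, b)


class TestImputation:
    def test_mean_and_mode_fill(self):
        schema = (
            VariableSpec("num", "continuous"),
            VariableSpec("cat", "categorical", categories=("yes", "no")),
        )
        df = pd.DataFrame(
            {
                "num": [1.0, 2.0, np.nan, 3.0],
                "cat": ["yes", "yes", "no", np.nan],
                "outcome": [0, 1, 0, 1],
            }
        )
        cohort = _cohort_from_frame(df, schema)
        model = fit_imputer(cohort)
        assert model.numeric_centers["num"] == pytest.approx(2.0)
        assert model.categorical_modes["cat"] == "yes"
        filled = apply_imputer(model, cohort)
        assert filled.data["num"].iloc[2] == pytest.approx(2.0)
        assert filled.data["cat"].iloc[3] == "yes"
        assert not filled.features().isna().any().any()

    def test_idempotent_and_identity_on_complete_data(self, mixed_cohort):
        model = fit_imputer(mixed_cohort)
        once = apply_imputer(model, mixed_cohort)
        twice = apply_imputer(model, once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        pd.testing.assert_frame_equal(once.data, mixed_cohort.data)

    def test_cross_center_application_rejected(self):
        a = make_mixed_cohort("A", seed=1)
        b = make_mixed_cohort("B", seed=2)
        with pytest.raises(CenterMismatchError):
            apply_imputer(fit_imputer(a), b)

    def test_all_missing_column_rejected(self):
        schema = (VariableSpec("num", "continuous"),)
        df = pd.DataFrame({"num": [np.nan, np.nan], "outcome": [0, 1]})
        with pytest.raises(DegenerateDataError):
            fit_imputer(_cohort_from_frame(df, schema))

    def test_json_roundtrip(self, mixed_cohort):
        from fedcohort.preprocessing import ImputationModel

        model = fit_imputer(mixed_cohort)
        assert ImputationModel.from_json(model.to_json()) == model


class TestScaling:
    def test_population_sd_hand_computed(self):
        schema = (VariableSpec("v", "continuous"),)
        df = pd.DataFrame({"v": [2.0, 4.0, 6.0], "outcome": [0, 1, 0]})
        cohort = _cohort_from_frame(df, schema)
        out = apply_scaler(fit_scaler(cohort), cohort)
        np.testing.assert_allclose(out["v"], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_onehot_complete_and_training_columns_standardized(self, mixed_cohort):
        model = fit_scaler(mixed_cohort)
        out = apply_scaler(model, mixed_cohort)
        smoking_cols = [c for c in out.columns if c.startswith("smoking=")]
        assert len(smoking_cols) == 3
        np.testing.assert_allclose(out[smoking_cols].sum(axis=1), 1.0)
        assert abs(out["age"].mean()) < 1e-10
        assert abs(out["age"].std(ddof=0) - 1) < 1e-10

    def test_idempotent_on_zscores(self):
        schema = (VariableSpec("v", "continuous", nonnegative=False),)
        rng = np.random.default_rng(0)
        z = rng.normal(size=50)
        z = (z - z.mean()) / z.std(ddof=0)
        df = pd.DataFrame({"v": z, "outcome": rng.integers(0, 2, 50)})
        cohort = _cohort_from_frame(df, schema)
        out = apply_scaler(fit_scaler(cohort), cohort)
        np.testing.assert_allclose(out["v"], z, atol=1e-12)

    def test_constant_column_and_unseen_category_rejected(self):
        schema = (
            VariableSpec("v", "continuous"),
            VariableSpec("c", "categorical", categories=("a", "b")),
        )
        df = pd.DataFrame({"v": [1.0, 1.0], "c": ["a", "b"], "outcome": [0, 1]})
        with pytest.raises(DegenerateDataError, match="constant"):
            fit_scaler(_cohort_from_frame(df, schema))
        df2 = pd.DataFrame({"v": [1.0, 2.0], "c": ["a", "b"], "outcome": [0, 1]})
        cohort = _cohort_from_frame(df2, schema)
        model = fit_scaler(cohort)
        df_bad = df2.copy()
        df_bad.loc[0, "c"] = "mystery"
        with pytest.raises(FormatError, match="c.*mystery"):
            apply_scaler(model, _cohort_from_frame(df_bad, schema))

    def test_tree_encoding_uses_schema_order_codes(self, mixed_cohort):
        out = encode_for_trees(mixed_cohort)
        assert set(out["copd"].unique()) <= {0.0, 1.0}
        assert set(out["smoking"].unique()) <= {0.0, 1.0, 2.0}
        np.testing.assert_allclose(out["age"], mixed_cohort.data["age"])


class TestImbalance:
    def test_balanced_classes_get_unit_weights(self):
        assert compute_class_weights([0, 0, 1, 1]) == {0: 1.0, 1: 1.0}

    def test_ninety_ten_weights(self):
        y = [0] * 90 + [1] * 10
        w = compute_class_weights(y)
        assert w[0] == pytest.approx(100 / 180)
        assert w[1] == pytest.approx(5.0)

    @pytest.mark.parametrize("n1", [1, 7, 25])
    def test_weighted_class_masses_equal(self, n1):
        y = np.array([0] * 50 + [1] * n1)
        w = compute_class_weights(y)
        assert w[0] * 50 == pytest.approx(w[1] * n1)
        assert sample_weights(y).sum() == pytest.approx(len(y))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            compute_class_weights([1, 1, 1])

    def test_oversampling_equalizes_without_touching_majority(self):
        cohort = make_mixed_cohort(seed=13, n=100, prevalence=0.1)
        y = cohort.outcomes()
        n0, n1 = int((y == 0).sum()), int((y == 1).sum())
        out = random_oversample(cohort, seed=0)
        assert out.oversampled
        y_out = out.outcomes()
        assert int((y_out == 0).sum()) == int((y_out == 1).sum()) == max(n0, n1)
        # majority rows untouched, in order
        majority = cohort.data[y == 0]
        pd.testing.assert_frame_equal(out.data[out.data["outcome"] == 0], majority)
        # every added row duplicates an existing minority row
        minority_ids = set(cohort.data[y == 1].index)
        assert set(out.data[out.data["outcome"] == 1].index) <= minority_ids
        # deterministic
        pd.testing.assert_frame_equal(out.data, random_oversample(cohort, seed=0).data)

    def test_already_balanced_unchanged(self):
        schema = (VariableSpec("v", "continuous"),)
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0], "outcome": [0, 0, 1, 1]})
        cohort = _cohort_from_frame(df, schema)
        out = random_oversample(cohort, seed=1)
        pd.testing.assert_frame_equal(out.data, cohort.data)
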