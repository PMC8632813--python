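import json

import numpy as np
import pytest

import fedcohort.learners as L
from fedcohort.errors import ContractError, DegenerateDataError, FormatError, IncompatibleModelError


def _fit_some(kind, X, y, seed=1):
    if kind in L.TREE_KINDS:
        model = L.init_model(kind, seed=seed)
        return L.extend_trees(model, X, y, k=8, center_id="A")
    model = L.init_model(kind, {"n_features": X.shape[1]}, seed=seed)
    return L.nn_update(model, X, y, epochs=5, center_id="A")


class TestInit:
    def test_tree_model_starts_empty(self):
        model = L.init_model("random_forest", seed=0)
        assert model.n_components == 0 and model.state is None

    def test_narrow_network_layer_sizes(self):
        model = L.init_model("nn_narrow", {"n_features": 16}, seed=0)
        assert model.state["sizes"] == [16, 8, 4, 1]

    def test_wide_network_layer_sizes(self):
        model = L.init_model("nn_wide", {"n_features": 16}, seed=0)
        assert model.state["sizes"] == [16, 100, 40, 1]

    def test_same_seed_identical_weights(self):
        a = L.init_model("nn_narrow", {"n_features": 5}, seed=42)
        b = L.init_model("nn_narrow", {"n_features": 5}, seed=42)
        for wa, wb in zip(a.state["W"], b.state["W"]):
            np.testing.assert_array_equal(wa, wb)

    def test_unknown_kind_and_hyperparameter_rejected(self):
        with pytest.raises(ContractError):
            L.init_model("svm")
        with pytest.raises(ContractError, match="gamma"):
            L.init_model("random_forest", {"gamma": 1.0})


class TestExtendTrees:
    @pytest.mark.parametrize("kind", L.TREE_KINDS)
    def test_prefix_predictions_immutable(self, kind, numeric_training_data):
        X, y, probe = numeric_training_data
        model = L.init_model(kind, seed=1)
        model = L.extend_trees(model, X, y, k=6, center_id="A")
        before = {m: L.prefix_predict(model, probe, m) for m in (1, 3, 6)}
        rng = np.random.default_rng(9)
        X2, y2 = rng.normal(size=(80, 6)), rng.integers(0, 2, 80)
        extended = L.extend_trees(model, X2, y2, k=6, center_id="B")
        for m, expected in before.items():
            np.testing.assert_array_equal(L.prefix_predict(extended, probe, m), expected)
        assert extended.n_components == 12

    @pytest.mark.parametrize("kind", L.TREE_KINDS)
    def test_staged_equals_batch_on_same_data(self, kind, numeric_training_data):
        X, y, probe = numeric_training_data
        empty = L.init_model(kind, seed=2)
        staged = L.extend_trees(L.extend_trees(empty, X, y, k=1), X, y, k=1)
        batch = L.extend_trees(empty, X, y, k=2)
        np.testing.assert_allclose(
            L.predict_proba(staged, probe), L.predict_proba(batch, probe), atol=1e-12
        )

    def test_provenance_alternates_centers(self, numeric_training_data):
        X, y, _ = numeric_training_data
        model = L.init_model("random_forest", seed=0)
        model = L.extend_trees(model, X, y, k=1, center_id="A")
        model = L.extend_trees(model, X, y, k=1, center_id="B")
        assert model.provenance == [(0, "A"), (1, "B")]
        assert L.components_per_center(model) == {"A": 1, "B": 1}

    def test_contract_violations(self, numeric_training_data):
        X, y, _ = numeric_training_data
        nn = L.init_model("nn_narrow", {"n_features": 6})
        with pytest.raises(ContractError):
            L.extend_trees(nn, X, y, k=1)
        with pytest.raises(ContractError):
            L.extend_trees(L.init_model("random_forest"), X, y, k=0)
        with pytest.raises(DegenerateDataError):
            L.extend_trees(L.init_model("random_forest"), X, np.zeros(len(y)), k=1)


class TestNetworkUpdates:
    def test_zero_learning_rate_leaves_weights_unchanged(self, numeric_training_data):
        X, y, _ = numeric_training_data
        model = L.init_model("nn_narrow", {"n_features": 6, "learning_rate": 0.0}, seed=5)
        updated = L.nn_update(model, X, y, epochs=4)
        for w0, w1 in zip(model.state["W"], updated.state["W"]):
            np.testing.assert_array_equal(w0, w1)

    def test_update_deterministic_from_same_state(self, numeric_training_data):
        X, y, _ = numeric_training_data
        model = L.init_model("nn_narrow", {"n_features": 6}, seed=5)
        a = L.nn_update(model, X, y, epochs=3, center_id="A")
        b = L.nn_update(model, X, y, epochs=3, center_id="A")
        for wa, wb in zip(a.state["W"], b.state["W"]):
            np.testing.assert_array_equal(wa, wb)

    def test_transfer_then_update_matches_no_transfer(self, numeric_training_data):
        X, y, _ = numeric_training_data
        model = L.nn_update(
            L.init_model("nn_narrow", {"n_features": 6}, seed=5), X, y, epochs=2
        )
        shipped = L.deserialize(L.serialize(model))
        for w0, w1 in zip(model.state["W"], shipped.state["W"]):
            np.testing.assert_array_equal(w0, w1)
        a = L.nn_update(shipped, X, y, epochs=2, center_id="B")
        b = L.nn_update(model, X, y, epochs=2, center_id="B")
        for wa, wb in zip(a.state["W"], b.state["W"]):
            np.testing.assert_array_equal(wa, wb)
        assert a.provenance == b.provenance

    def test_dimension_mismatch_rejected(self, numeric_training_data):
        X, y, _ = numeric_training_data
        model = L.init_model("nn_narrow", {"n_features": 4})
        with pytest.raises(ContractError, match="dimension"):
            L.nn_update(model, X, y, epochs=1)


class TestPrediction:
    @pytest.mark.parametrize("kind", L.LEARNER_KINDS)
    def test_probabilities_within_unit_interval(self, kind, numeric_training_data):
        X, y, probe = numeric_training_data
        model = _fit_some(kind, X, y)
        p = L.predict_proba(model, probe)
        assert p.shape == (len(probe),)
        assert np.all(p >= 0) and np.all(p <= 1)

    def test_zero_tree_model_cannot_predict(self, numeric_training_data):
        _, _, probe = numeric_training_data
        with pytest.raises(ContractError):
            L.predict_proba(L.init_model("random_forest"), probe)

    def test_prefix_bounds_checked(self, numeric_training_data):
        X, y, probe = numeric_training_data
        model = _fit_some("random_forest", X, y)
        with pytest.raises(ContractError):
            L.prefix_predict(model, probe, model.n_components + 1)


class TestSerialization:
    @pytest.mark.parametrize("kind", L.LEARNER_KINDS)
    def test_roundtrip_prediction_identity(self, kind, numeric_training_data):
        X, y, probe = numeric_training_data
        model = _fit_some(kind, X, y)
        blob = L.serialize(model)
        restored = L.deserialize(blob)
        np.testing.assert_array_equal(
            L.predict_proba(model, probe), L.predict_proba(restored, probe)
        )
        assert restored.provenance == model.provenance

    def test_corrupted_blob_raises_parse_error(self):
        with pytest.raises(FormatError):
            L.deserialize("{not json")
        with pytest.raises(FormatError):
            L.deserialize(json.dumps({"kind": "random_forest"}))

    def test_version_mismatch_is_explicit(self, numeric_training_data):
        X, y, _ = numeric_training_data
        blob = json.loads(L.serialize(_fit_some("random_forest", X, y)))
        blob["format_version"] = 99
        with pytest.raises(IncompatibleModelError):
            L.deserialize(json.dumps(blob))

    def test_envelope_provenance_audits_per_center_counts(self, numeric_training_data):
        X, y, _ = numeric_training_data
        model = L.init_model("boosted_trees_x", seed=0)
        for cid in ("A", "B", "A", "B"):
            model = L.extend_trees(model, X, y, k=2, center_id=cid)
        restored = L.deserialize(L.serialize(model))
        assert L.components_per_center(restored) == {"A": 4, "B": 4}


class TestFitLocal:
    @pytest.mark.parametrize("imbalance", ["class_weighting", "random_oversampling"])
    def test_fit_local_on_mixed_cohort(self, imbalance, mixed_cohort):
        for kind in ("random_forest", "nn_narrow"):
            fitted = L.fit_local(
                mixed_cohort, kind, {"n_estimators": 10} if kind == "random_forest" else {"epochs": 20},
                imbalance, seed=0
            )
            p = fitted.predict_proba(mixed_cohort)
            assert p.shape == (mixed_cohort.n_rows,)
            assert (fitted.scaler is None) == (kind in L.TREE_KINDS)
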