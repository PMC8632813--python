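"""Uniform learner contract for the distributed protocols.

Five binary classifiers sit behind one interface: a random forest, two
gradient-boosted-tree variants, and two fully-connected networks (narrow:
hidden layers of 8 and 4 units; wide: 100 and 40). The distributed
protocols need three capabilities ordinary estimator APIs do not promise:

* **Serializable state** — a model must cross the center boundary as a
  self-describing text envelope and predict identically after the trip.
* **Append-only tree growth** — a center may add trees to an ensemble it
  received, but the trees built elsewhere must remain byte-identical; the
  prediction of any tree prefix is invariant to later extensions. Boosted
  variants fit new trees against the running ensemble's predictions.
* **Resumable, seeded network updates** — gradient steps continue from the
  exact optimizer and dropout-stream state the envelope carries.

The forest and boosted backends are scikit-learn, XGBoost and LightGBM
(behind the contract; warm-start/continued-training modes provide the
append semantics). The network is a small NumPy implementation — ReLU
hidden layers, inverted dropout between them, sigmoid output, weighted
binary cross-entropy, full-batch Adam — because resumable seeded updates
with per-sample weights and dropout are the contract here, not a large
architecture. Every model addition carries provenance, so "how many trees
did each center contribute" is auditable after the fact.
"""

from __future__ import annotations

import base64
import copy
import json
import pickle
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateDataError, FormatError, IncompatibleModelError

__all__ = [
    "LEARNER_KINDS",
    "TREE_KINDS",
    "NN_KINDS",
    "NN_HIDDEN_SIZES",
    "DEFAULT_HYPERPARAMS",
    "DEFAULT_GRID",
    "ExchangeableModel",
    "init_model",
    "extend_trees",
    "nn_update",
    "predict_proba",
    "prefix_predict",
    "serialize",
    "deserialize",
    "components_per_center",
    "fit_local",
    "FittedLocalModel",
]

FORMAT_VERSION = 1

TREE_KINDS = ("random_forest", "boosted_trees_x", "boosted_trees_c")
NN_KINDS = ("nn_narrow", "nn_wide")
LEARNER_KINDS = TREE_KINDS + NN_KINDS

NN_HIDDEN_SIZES = {"nn_narrow": (8, 4), "nn_wide": (100, 40)}

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "random_forest": {"n_estimators": 100, "max_depth": None, "max_features": "sqrt"},
    "boosted_trees_x": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
    "boosted_trees_c": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
    "nn_narrow": {"epochs": 200, "learning_rate": 1e-3, "dropout": 0.2},
    "nn_wide": {"epochs": 200, "learning_rate": 1e-3, "dropout": 0.2},
}

DEFAULT_GRID: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [100, 300], "max_features": ["sqrt", None]},
    "boosted_trees_x": {
        "max_depth": [2, 3, 4],
        "learning_rate": [0.05, 0.1],
        "n_estimators": [50, 100, 200],
    },
    "boosted_trees_c": {
        "max_depth": [2, 3, 4],
        "learning_rate": [0.05, 0.1],
        "n_estimators": [50, 100, 200],
    },
    "nn_narrow": {"dropout": [0.0, 0.2], "epochs": [50, 200]},
    "nn_wide": {"dropout": [0.0, 0.2], "epochs": [50, 200]},
}

_ALLOWED_HP = {
    "random_forest": {"n_estimators", "max_depth", "max_features"},
    "boosted_trees_x": {"n_estimators", "max_depth", "learning_rate"},
    "boosted_trees_c": {"n_estimators", "max_depth", "learning_rate"},
    "nn_narrow": {"epochs", "learning_rate", "dropout", "n_features"},
    "nn_wide": {"epochs", "learning_rate", "dropout", "n_features"},
}


@dataclass
class ExchangeableModel:
    """A learner plus the provenance of every component it carries.

    ``provenance`` holds one ``(component_index, center_id)`` pair per tree
    for tree kinds, or one ``(version, center_id)`` pair per completed
    update round for network kinds.
    """

    kind: str
    hyperparams: dict
    seed: int
    provenance: list = field(default_factory=list)
    state: object | None = None

    @property
    def n_components(self) -> int:
        return len(self.provenance)

    @property
    def is_tree(self) -> bool:
        return self.kind in TREE_KINDS


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    return np.asarray(X, dtype=float)


def init_model(kind: str, hyperparams: Mapping | None = None, seed: int = 0) -> ExchangeableModel:
    """Fresh model: zero trees, or freshly initialized network weights.

    Network kinds initialize eagerly when ``n_features`` is among the
    hyperparameters, else lazily at the first update.
    """
    if kind not in LEARNER_KINDS:
        raise ContractError(f"unknown learner kind {kind!r}")
    hp = dict(DEFAULT_HYPERPARAMS[kind])
    if hyperparams:
        unknown = set(hyperparams) - _ALLOWED_HP[kind]
        if unknown:
            raise ContractError(f"unknown hyperparameter(s) for {kind}: {sorted(unknown)}")
        hp.update(hyperparams)
    model = ExchangeableModel(kind=kind, hyperparams=hp, seed=int(seed))
    if kind in NN_KINDS and hp.get("n_features"):
        model.state = _mlp_init(int(hp["n_features"]), NN_HIDDEN_SIZES[kind], seed)
    return model


# ---------------------------------------------------------------------------
# tree backends


def _check_training_data(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("training chunk must contain both classes")


def _rf_extend(model, X, y, w, k):
    from sklearn.ensemble import RandomForestClassifier

    hp = model.hyperparams
    if model.state is None:
        rf = RandomForestClassifier(
            n_estimators=k,
            max_depth=hp["max_depth"],
            max_features=hp["max_features"],
            warm_start=True,
            random_state=model.seed,
            n_jobs=1,
        )
    else:
        rf = pickle.loads(pickle.dumps(model.state))
        rf.set_params(n_estimators=rf.n_estimators + k)
    rf.fit(X, y, sample_weight=w)
    return rf


def _xgb_params(model) -> dict:
    hp = model.hyperparams
    return {
        "objective": "binary:logistic",
        "max_depth": int(hp["max_depth"]),
        "eta": float(hp["learning_rate"]),
        "base_score": 0.5,  # data-estimated base scores break cross-center coherence
        "tree_method": "hist",
        "nthread": 1,
        "seed": model.seed,
        "verbosity": 0,
    }


def _xgb_extend(model, X, y, w, k):
    import xgboost as xgb

    dtrain = xgb.DMatrix(X, label=y, weight=w)
    prev = None
    if model.state is not None:
        prev = bytearray(model.state.save_raw())
    return xgb.train(_xgb_params(model), dtrain, num_boost_round=k, xgb_model=prev)


def _lgb_params(model) -> dict:
    hp = model.hyperparams
    depth = int(hp["max_depth"])
    return {
        "objective": "binary",
        "max_depth": depth,
        "num_leaves": 2**depth,
        "learning_rate": float(hp["learning_rate"]),
        "min_data_in_leaf": 5,
        "boost_from_average": False,  # keep the 0-score baseline at p=0.5
        "deterministic": True,
        "force_row_wise": True,
        "num_threads": 1,
        "seed": model.seed,
        "verbose": -1,
    }


def _lgb_extend(model, X, y, w, k):
    import lightgbm as lgb

    dtrain = lgb.Dataset(X, label=y, weight=w, params={"verbose": -1})
    init = None
    if model.state is not None:
        # round-trip through text so the caller's booster is never mutated
        init = lgb.Booster(model_str=model.state.model_to_string())
    return lgb.train(
        _lgb_params(model),
        dtrain,
        num_boost_round=k,
        init_model=init,
        keep_training_booster=True,
    )


def extend_trees(
    model: ExchangeableModel,
    features,
    outcomes,
    sample_weights=None,
    k: int = 1,
    center_id: str = "?",
) -> ExchangeableModel:
    """Append ``k`` trees fitted on local data; earlier trees are untouched.

    For boosted kinds the new trees fit the loss gradient at the current
    ensemble's predictions; for the forest they are independent bootstrap
    trees. Returns a new model — the input is not mutated.
    """
    if model.kind not in TREE_KINDS:
        raise ContractError(f"extend_trees on non-tree kind {model.kind!r}")
    if k < 1:
        raise ContractError("k must be >= 1")
    X = _as_array(features)
    y = np.asarray(outcomes, dtype=int)
    _check_training_data(y)
    w = None if sample_weights is None else np.asarray(sample_weights, dtype=float)
    if model.kind == "random_forest":
        state = _rf_extend(model, X, y, w, k)
    elif model.kind == "boosted_trees_x":
        state = _xgb_extend(model, X, y, w, k)
    else:
        state = _lgb_extend(model, X, y, w, k)
    start = model.n_components
    return ExchangeableModel(
        kind=model.kind,
        hyperparams=dict(model.hyperparams),
        seed=model.seed,
        provenance=list(model.provenance) + [(start + i, str(center_id)) for i in range(k)],
        state=state,
    )


# ---------------------------------------------------------------------------
# network backend (NumPy MLP)


def _mlp_init(n_features: int, hidden: tuple[int, int], seed: int) -> dict:
    rng = np.random.default_rng(seed)
    sizes = [n_features, *hidden, 1]
    W, b = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        b.append(np.zeros(fan_out))
    return {
        "sizes": sizes,
        "W": W,
        "b": b,
        "mW": [np.zeros_like(w) for w in W],
        "vW": [np.zeros_like(w) for w in W],
        "mb": [np.zeros_like(v) for v in b],
        "vb": [np.zeros_like(v) for v in b],
        "t": 0,
        "rng_state": rng.bit_generator.state,
    }


def _mlp_forward(state: dict, X: np.ndarray) -> np.ndarray:
    h = X
    n_layers = len(state["W"])
    for i, (W, b) in enumerate(zip(state["W"], state["b"])):
        z = h @ W + b
        h = np.maximum(z, 0.0) if i < n_layers - 1 else 1.0 / (1.0 + np.exp(-z))
    return h[:, 0]


def nn_update(
    model: ExchangeableModel,
    features,
    outcomes,
    sample_weights=None,
    epochs: int = 1,
    center_id: str = "?",
) -> ExchangeableModel:
    """Advance the network by full-batch Adam epochs on local data.

    Inverted dropout is applied between the hidden layers during training
    only, with masks drawn from the random stream the model itself carries,
    so an update is reproducible from the serialized state alone. Returns a
    new model; the input is not mutated.
    """
    if model.kind not in NN_KINDS:
        raise ContractError(f"nn_update on non-network kind {model.kind!r}")
    X = _as_array(features)
    y = np.asarray(outcomes, dtype=float)
    state = (
        copy.deepcopy(model.state)
        if model.state is not None
        else _mlp_init(X.shape[1], NN_HIDDEN_SIZES[model.kind], model.seed)
    )
    if X.shape[1] != state["sizes"][0]:
        raise ContractError(
            f"feature dimension {X.shape[1]} != network input {state['sizes'][0]}"
        )
    w = np.ones(len(y)) if sample_weights is None else np.asarray(sample_weights, float)
    w = w / w.mean()
    lr = float(model.hyperparams["learning_rate"])
    drop = float(model.hyperparams["dropout"])
    rng = np.random.default_rng()
    rng.bit_generator.state = state["rng_state"]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n = len(y)
    W, b = state["W"], state["b"]
    for _ in range(int(epochs)):
        # forward with dropout after each hidden activation
        acts = [X]
        masks = []
        h = X
        for i in range(len(W) - 1):
            h = np.maximum(h @ W[i] + b[i], 0.0)
            if drop > 0:
                mask = (rng.random(h.shape) >= drop) / (1.0 - drop)
                h = h * mask
            else:
                mask = None
            masks.append(mask)
            acts.append(h)
        z_out = h @ W[-1] + b[-1]
        p = 1.0 / (1.0 + np.exp(-z_out[:, 0]))
        # weighted BCE gradient wrt output logit
        delta = (w * (p - y) / n)[:, None]
        gW = [None] * len(W)
        gb = [None] * len(b)
        for i in range(len(W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ W[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0)
        state["t"] += 1
        t = state["t"]
        for i in range(len(W)):
            for g, theta, m, v in (
                (gW[i], W, state["mW"], state["vW"]),
                (gb[i], b, state["mb"], state["vb"]),
            ):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g**2
                m_hat = m[i] / (1 - beta1**t)
                v_hat = v[i] / (1 - beta2**t)
                theta[i] = theta[i] - lr * m_hat / (np.sqrt(v_hat) + eps)
    state["rng_state"] = rng.bit_generator.state
    return ExchangeableModel(
        kind=model.kind,
        hyperparams=dict(model.hyperparams),
        seed=model.seed,
        provenance=list(model.provenance) + [(model.n_components, str(center_id))],
        state=state,
    )


# ---------------------------------------------------------------------------
# prediction


def predict_proba(model: ExchangeableModel, features) -> np.ndarray:
    """Per-row probability of the positive outcome, in [0, 1]."""
    X = _as_array(features)
    if model.is_tree:
        if model.state is None or model.n_components == 0:
            raise ContractError("cannot predict with a zero-tree ensemble")
        if model.kind == "random_forest":
            return model.state.predict_proba(X)[:, 1]
        if model.kind == "boosted_trees_x":
            import xgboost as xgb

            return model.state.predict(xgb.DMatrix(X))
        return model.state.predict(X)
    if model.state is None:
        raise ContractError("network not initialized")
    return _mlp_forward(model.state, X)


def prefix_predict(model: ExchangeableModel, features, m: int) -> np.ndarray:
    """Prediction of the first ``m`` trees only — the prefix-audit primitive."""
    if not model.is_tree:
        raise ContractError("prefix prediction is defined for tree kinds only")
    if not 1 <= m <= model.n_components:
        raise ContractError(f"prefix length {m} outside 1..{model.n_components}")
    X = _as_array(features)
    if model.kind == "random_forest":
        probs = [est.predict_proba(X)[:, 1] for est in model.state.estimators_[:m]]
        return np.mean(probs, axis=0)
    if model.kind == "boosted_trees_x":
        import xgboost as xgb

        return model.state.predict(xgb.DMatrix(X), iteration_range=(0, m))
    return np.asarray(model.state.predict(X, num_iteration=m))


def components_per_center(model: ExchangeableModel) -> dict[str, int]:
    """Audit: how many trees (or update rounds) each center contributed."""
    out: dict[str, int] = {}
    for _, cid in model.provenance:
        out[cid] = out.get(cid, 0) + 1
    return out


# ---------------------------------------------------------------------------
# serialization


def _state_to_envelope(model: ExchangeableModel) -> dict | None:
    if model.state is None:
        return None
    if model.kind == "random_forest":
        return {
            "backend": "sklearn-rf",
            "pickle_b64": base64.b64encode(pickle.dumps(model.state)).decode(),
        }
    if model.kind == "boosted_trees_x":
        raw = model.state.save_raw()
        return {"backend": "xgboost", "raw_b64": base64.b64encode(bytes(raw)).decode()}
    if model.kind == "boosted_trees_c":
        return {"backend": "lightgbm", "model_str": model.state.model_to_string()}
    s = model.state
    return {
        "backend": "numpy-mlp",
        "sizes": list(s["sizes"]),
        "W": [w.tolist() for w in s["W"]],
        "b": [v.tolist() for v in s["b"]],
        "mW": [w.tolist() for w in s["mW"]],
        "vW": [w.tolist() for w in s["vW"]],
        "mb": [v.tolist() for v in s["mb"]],
        "vb": [v.tolist() for v in s["vb"]],
        "t": s["t"],
        "rng_state": _rng_state_to_json(s["rng_state"]),
    }


def _rng_state_to_json(state: dict) -> dict:
    return json.loads(json.dumps(state, default=int))


def _state_from_envelope(kind: str, blob: dict | None):
    if blob is None:
        return None
    backend = blob.get("backend")
    if kind == "random_forest" and backend == "sklearn-rf":
        return pickle.loads(base64.b64decode(blob["pickle_b64"]))
    if kind == "boosted_trees_x" and backend == "xgboost":
        import xgboost as xgb

        booster = xgb.Booster()
        booster.load_model(bytearray(base64.b64decode(blob["raw_b64"])))
        return booster
    if kind == "boosted_trees_c" and backend == "lightgbm":
        import lightgbm as lgb

        return lgb.Booster(model_str=blob["model_str"])
    if kind in NN_KINDS and backend == "numpy-mlp":
        state = {
            "sizes": list(blob["sizes"]),
            "W": [np.array(w) for w in blob["W"]],
            "b": [np.array(v) for v in blob["b"]],
            "mW": [np.array(w) for w in blob["mW"]],
            "vW": [np.array(w) for w in blob["vW"]],
            "mb": [np.array(v) for v in blob["mb"]],
            "vb": [np.array(v) for v in blob["vb"]],
            "t": int(blob["t"]),
            "rng_state": blob["rng_state"],
        }
        return state
    raise FormatError(f"state backend {backend!r} does not match kind {kind!r}")


def serialize(model: ExchangeableModel) -> str:
    """Self-describing JSON envelope — the only artifact allowed across centers."""
    return json.dumps(
        {
            "format_version": FORMAT_VERSION,
            "kind": model.kind,
            "seed": model.seed,
            "hyperparams": model.hyperparams,
            "provenance": [[int(i), str(c)] for i, c in model.provenance],
            "state": _state_to_envelope(model),
        }
    )


def deserialize(blob: str) -> ExchangeableModel:
    """Parse an envelope; corrupted input raises, it never mispredicts silently."""
    try:
        d = json.loads(blob)
    except (json.JSONDecodeError, TypeError) as exc:
        raise FormatError(f"not a valid model envelope: {exc}") from exc
    if not isinstance(d, dict) or "format_version" not in d:
        raise FormatError("not a model envelope (no format_version)")
    if d["format_version"] != FORMAT_VERSION:
        raise IncompatibleModelError(
            f"envelope format {d['format_version']} unsupported (want {FORMAT_VERSION})"
        )
    kind = d["kind"]
    if kind not in LEARNER_KINDS:
        raise FormatError(f"unknown learner kind {kind!r} in envelope")
    return ExchangeableModel(
        kind=kind,
        hyperparams=dict(d["hyperparams"]),
        seed=int(d["seed"]),
        provenance=[(int(i), str(c)) for i, c in d["provenance"]],
        state=_state_from_envelope(kind, d["state"]),
    )


# ---------------------------------------------------------------------------
# plain local training (the mono-center primitive)


@dataclass
class FittedLocalModel:
    """A trained model bundled with the encoding it expects.

    Tree kinds carry no scaler (they see integer category codes); network
    kinds carry the standardizer/one-hot layout fitted at their home
    center, so the bundle can score any cohort with the shared schema.
    """

    model: ExchangeableModel
    scaler: object | None = None

    def encode(self, cohort) -> pd.DataFrame:
        from .preprocessing import apply_scaler, encode_for_trees

        if self.scaler is not None:
            return apply_scaler(self.scaler, cohort)
        return encode_for_trees(cohort)

    def predict_proba(self, cohort) -> np.ndarray:
        return predict_proba(self.model, self.encode(cohort))


def fit_local(
    cohort,
    kind: str,
    hyperparams: Mapping | None = None,
    imbalance: str = "class_weighting",
    seed: int = 0,
) -> FittedLocalModel:
    """Ordinary single-center training with the chosen imbalance strategy.

    This is both the mono-center baseline and the local stage of stacking:
    trees are grown in one shot to ``n_estimators``; networks train for
    ``epochs`` full-batch epochs on standardized one-hot features.
    """
    from .preprocessing import apply_scaler, fit_scaler, random_oversample, sample_weights

    if imbalance not in ("class_weighting", "random_oversampling"):
        raise ContractError(f"unknown imbalance strategy {imbalance!r}")
    model = init_model(kind, hyperparams, seed)
    scaler = fit_scaler(cohort) if kind in NN_KINDS else None
    train = cohort
    weights = None
    if imbalance == "random_oversampling":
        train = random_oversample(cohort, seed)
    else:
        weights = sample_weights(train.outcomes())
    y = train.outcomes().to_numpy(dtype=int)
    if kind in NN_KINDS:
        X = apply_scaler(scaler, train)
        model = init_model(kind, {**(hyperparams or {}), "n_features": X.shape[1]}, seed)
        model = nn_update(
            model, X, y, weights,
            epochs=model.hyperparams["epochs"],
            center_id=cohort.center_id,
        )
    else:
        from .preprocessing import encode_for_trees

        X = encode_for_trees(train)
        model = extend_trees(
            model, X, y, weights,
            k=model.hyperparams["n_estimators"],
            center_id=cohort.center_id,
        )
    return FittedLocalModel(model=model, scaler=scaler)
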