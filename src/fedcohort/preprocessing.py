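"""Cohort preparation: exclusions, per-center imputation, encoding, imbalance.

The locality rule of federated clinical modelling is enforced structurally
here: an :class:`ImputationModel` remembers which center it was fitted on
and refuses to impute another center's rows. Imputation is simple
(column mean / mode); standardization plus full one-hot encoding is applied
only for the neural networks, while tree learners receive integer category
codes. Two class-imbalance strategies are supported: balanced class weights
and random oversampling of the minority class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    CenterMismatchError,
    DegenerateDataError,
    FormatError,
    SchemaConflictError,
)
from .synthetic_cohort import OUTCOME_COL, CohortTable, VariableSpec

__all__ = [
    "ImputationModel",
    "ScalerModel",
    "IMBALANCE_STRATEGIES",
    "exclude_patients",
    "intersect_variables",
    "fit_imputer",
    "apply_imputer",
    "fit_scaler",
    "apply_scaler",
    "encode_for_trees",
    "compute_class_weights",
    "sample_weights",
    "random_oversample",
]

#: the two imbalance-handling strategies applied during training
IMBALANCE_STRATEGIES = ("class_weighting", "random_oversampling")


def exclude_patients(cohort: CohortTable) -> CohortTable:
    """Drop rows with a missing outcome or more than half their features missing.

    The boundary is strict: a row missing exactly 50% of its features is
    retained. Row order is preserved.
    """
    feats = cohort.features()
    frac_missing = feats.isna().mean(axis=1)
    keep = cohort.data[OUTCOME_COL].notna() & (frac_missing <= 0.5)
    return cohort.replace(cohort.data.loc[keep])


def intersect_variables(
    schema_a: Sequence[VariableSpec], schema_b: Sequence[VariableSpec]
) -> tuple[VariableSpec, ...]:
    """Variables available in both schemas, in ``schema_a`` order.

    A name shared with a different kind is a modelling conflict, not a
    silent drop.
    """
    by_name_b = {v.name: v for v in schema_b}
    out = []
    for v in schema_a:
        other = by_name_b.get(v.name)
        if other is None:
            continue
        if other.kind != v.kind:
            raise SchemaConflictError(
                f"variable {v.name!r} is {v.kind} in one schema, {other.kind} in the other"
            )
        out.append(v)
    return tuple(out)


@dataclass
class ImputationModel:
    """Column means / modes of one center, usable only on that center."""

    center_id: str
    numeric_centers: dict[str, float]
    categorical_modes: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "center_id": self.center_id,
                "numeric_centers": self.numeric_centers,
                "categorical_modes": self.categorical_modes,
            }
        )

    @classmethod
    def from_json(cls, blob: str) -> "ImputationModel":
        d = json.loads(blob)
        return cls(d["center_id"], d["numeric_centers"], d["categorical_modes"])


def fit_imputer(cohort: CohortTable) -> ImputationModel:
    """Column mean (continuous) / most frequent category (categorical) per variable.

    Mode ties break toward the category listed first in the schema, for
    determinism. A column with no observed value has no central tendency
    and is an error.
    """
    numeric: dict[str, float] = {}
    modes: dict[str, str] = {}
    for var in cohort.schema:
        col = cohort.data[var.name]
        observed = col.dropna()
        if observed.empty:
            raise DegenerateDataError(
                f"cannot impute {var.name!r}: no observed values at center "
                f"{cohort.center_id}"
            )
        if var.kind == "continuous":
            numeric[var.name] = float(observed.astype(float).mean())
        else:
            counts = observed.value_counts()
            best = max(
                var.categories,
                key=lambda c: (counts.get(c, 0), -var.categories.index(c)),
            )
            modes[var.name] = best
    return ImputationModel(cohort.center_id, numeric, modes)


def apply_imputer(model: ImputationModel, cohort: CohortTable) -> CohortTable:
    """Fill missing feature values with the center's own means/modes."""
    if model.center_id != cohort.center_id:
        raise CenterMismatchError(
            f"imputer fitted on center {model.center_id!r} applied to "
            f"{cohort.center_id!r}"
        )
    data = cohort.data.copy()
    for var in cohort.schema:
        fill = (
            model.numeric_centers[var.name]
            if var.kind == "continuous"
            else model.categorical_modes[var.name]
        )
        data[var.name] = data[var.name].fillna(fill)
    return cohort.replace(data)


@dataclass
class ScalerModel:
    """Standardization stats plus a fixed one-hot layout for NN inputs."""

    numeric_means: dict[str, float]
    numeric_sds: dict[str, float]
    onehot_layout: dict[str, list[str]]

    @property
    def output_columns(self) -> list[str]:
        cols = []
        for name in self.numeric_means:
            cols.append(name)
        for name, cats in self.onehot_layout.items():
            cols.extend(f"{name}={c}" for c in cats)
        return cols

    def to_json(self) -> str:
        return json.dumps(
            {
                "numeric_means": self.numeric_means,
                "numeric_sds": self.numeric_sds,
                "onehot_layout": self.onehot_layout,
            }
        )

    @classmethod
    def from_json(cls, blob: str) -> "ScalerModel":
        d = json.loads(blob)
        return cls(d["numeric_means"], d["numeric_sds"], d["onehot_layout"])


def fit_scaler(cohort: CohortTable) -> ScalerModel:
    """Per-column mean and population sd; one-hot layout from the schema.

    The layout lists every schema category (no dropped level) so the encoded
    width is identical across centers even when a rare category is absent
    locally. Constant numeric columns are rejected: they cannot be scaled
    to unit variance.
    """
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    layout: dict[str, list[str]] = {}
    for var in cohort.schema:
        if var.kind == "continuous":
            col = cohort.data[var.name].astype(float)
            if col.isna().any():
                raise DegenerateDataError(f"{var.name}: impute before scaling")
            mu = float(col.mean())
            sd = float(col.std(ddof=0))
            if sd == 0:
                raise DegenerateDataError(f"{var.name}: constant column cannot be scaled")
            means[var.name], sds[var.name] = mu, sd
        else:
            layout[var.name] = list(var.categories)
    return ScalerModel(means, sds, layout)


def apply_scaler(model: ScalerModel, cohort: CohortTable) -> pd.DataFrame:
    """Standardize continuous columns and one-hot encode categorical ones.

    Output column order is fixed by the model (continuous first, then the
    indicator blocks). An observed category outside the layout is an error
    naming the variable and label.
    """
    out: dict[str, np.ndarray] = {}
    for name, mu in model.numeric_means.items():
        col = cohort.data[name].astype(float).to_numpy()
        out[name] = (col - mu) / model.numeric_sds[name]
    for name, cats in model.onehot_layout.items():
        col = cohort.data[name]
        if col.isna().any():
            raise DegenerateDataError(f"{name}: impute before encoding")
        unseen = set(col.unique()) - set(cats)
        if unseen:
            raise FormatError(
                f"variable {name!r}: unseen category label(s) {sorted(map(str, unseen))}"
            )
        for c in cats:
            out[f"{name}={c}"] = (col == c).to_numpy(dtype=float)
    return pd.DataFrame(out, index=cohort.data.index)[model.output_columns]


def encode_for_trees(cohort: CohortTable) -> pd.DataFrame:
    """Numeric view for tree learners: categories become schema-order codes."""
    out: dict[str, np.ndarray] = {}
    for var in cohort.schema:
        col = cohort.data[var.name]
        if var.kind == "continuous":
            out[var.name] = col.astype(float).to_numpy()
        else:
            mapping = {c: i for i, c in enumerate(var.categories)}
            out[var.name] = col.map(mapping).astype(float).to_numpy()
    return pd.DataFrame(out, index=cohort.data.index)


def compute_class_weights(outcomes: Sequence[int]) -> dict[int, float]:
    """Balanced heuristic w_c = n_total / (2 * n_c): equal weighted class mass."""
    y = np.asarray(outcomes)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise DegenerateDataError("class weights undefined with a single class")
    n = n0 + n1
    return {0: n / (2 * n0), 1: n / (2 * n1)}


def sample_weights(outcomes: Sequence[int]) -> np.ndarray:
    """Per-row weights realizing :func:`compute_class_weights`."""
    w = compute_class_weights(outcomes)
    y = np.asarray(outcomes)
    return np.where(y == 1, w[1], w[0]).astype(float)


def random_oversample(cohort: CohortTable, seed: int) -> CohortTable:
    """Duplicate random minority-class rows until the classes balance.

    Majority rows are untouched; every added row is an exact copy of an
    existing minority row, so the result carries duplicated patient ids and
    is flagged ``oversampled``.
    """
    y = cohort.outcomes().to_numpy()
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 == 0 or n1 == 0:
        raise DegenerateDataError("oversampling undefined with a single class")
    if n0 == n1:
        return cohort.replace(cohort.data, oversampled=True)
    minority = 1 if n1 < n0 else 0
    need = abs(n0 - n1)
    rng = np.random.default_rng(seed)
    pool = cohort.data[cohort.data[OUTCOME_COL] == minority]
    extra = pool.iloc[rng.integers(0, len(pool), size=need)]
    data = pd.concat([cohort.data, extra])
    return cohort.replace(data, oversampled=True)
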