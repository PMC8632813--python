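"""Cyclical weight transfer: one model, passed around the centers.

A single model visits the centers in a fixed cycle, starting at the center
with the most data. At each visit the acting center applies its imbalance
strategy to its own training rows, performs one local update (a block of
new trees, or a block of training epochs for the networks), measures its
validation loss, and hands the serialized model to the next center. The
only artifact that ever crosses the center boundary is the model envelope
— the training loop below literally round-trips the model through
:func:`~fedcohort.learners.serialize` at every hand-over.

Training stops at an iteration cap (default 500 center-updates) or when
every center has gone ``patience`` (default 10) consecutive visits without
a strict improvement of its own validation loss — the plateau must hold at
*both* centers, a single stalled center does not stop the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from . import learners as L
from .errors import ContractError, DegenerateDataError
from .preprocessing import (
    apply_scaler,
    encode_for_trees,
    fit_scaler,
    random_oversample,
    sample_weights,
)
from .synthetic_cohort import CohortTable

__all__ = [
    "CyclicalConfig",
    "TrainingLedger",
    "StopDecision",
    "order_centers",
    "split_validation",
    "check_stopping",
    "cwt_train",
]


@dataclass
class CyclicalConfig:
    """Knobs of the cyclical protocol.

    ``trees_per_cycle`` / ``epochs_per_cycle`` is the size of one local
    update for tree / network kinds respectively (default 1, the smallest
    exchangeable unit); ``validation_fraction`` is carved once per center
    before the first cycle and reused throughout.
    """

    max_iterations: int = 500
    patience: int = 10
    trees_per_cycle: int = 1
    epochs_per_cycle: int = 1
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1 or self.patience < 1:
            raise ContractError("max_iterations and patience must be >= 1")


@dataclass
class TrainingLedger:
    """Append-only record of per-center validation losses and stopping state."""

    centers: list[str]
    losses: dict[str, list[float]] = field(default_factory=dict)
    best_loss: dict[str, float] = field(default_factory=dict)
    cycles_since_improvement: dict[str, int] = field(default_factory=dict)
    iteration_count: int = 0
    stop_reason: str = "running"
    _history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.centers:
            self.losses.setdefault(c, [])
            self.best_loss.setdefault(c, math.inf)
            self.cycles_since_improvement.setdefault(c, 0)

    def record(self, center: str, loss: float) -> None:
        if self.stop_reason != "running":
            raise ContractError("ledger is closed; no updates after stopping")
        self.losses[center].append(float(loss))
        if loss < self.best_loss[center]:
            self.best_loss[center] = float(loss)
            self.cycles_since_improvement[center] = 0
        else:
            self.cycles_since_improvement[center] += 1
        self.iteration_count += 1
        self._history.append(
            {
                "iteration": self.iteration_count,
                "center": center,
                "validation_loss": float(loss),
                **{
                    f"cycles_since_improvement_{c}": self.cycles_since_improvement[c]
                    for c in self.centers
                },
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._history)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class StopDecision(NamedTuple):
    stop: bool
    reason: str | None


def order_centers(cohorts: Mapping[str, CohortTable]) -> list[str]:
    """Largest cohort first (it opens the training); ties by center label."""
    return sorted(cohorts, key=lambda c: (-cohorts[c].n_rows, c))


def split_validation(
    cohort: CohortTable, fraction: float, seed: int
) -> tuple[CohortTable, CohortTable]:
    """Outcome-stratified train/validation split, fixed for the whole run."""
    from sklearn.model_selection import train_test_split

    if not 0 < fraction < 1:
        raise ContractError("validation fraction must lie strictly in (0, 1)")
    y = cohort.outcomes().to_numpy(dtype=int)
    idx = np.arange(cohort.n_rows)
    try:
        train_idx, val_idx = train_test_split(
            idx, test_size=fraction, stratify=y, random_state=seed
        )
    except ValueError as exc:
        raise DegenerateDataError(
            f"cannot stratify a validation split at fraction {fraction}: {exc}; "
            "a larger cohort is needed"
        ) from exc
    train_idx.sort()
    val_idx.sort()
    for part in (train_idx, val_idx):
        if len(np.unique(y[part])) < 2:
            raise DegenerateDataError(
                "a class is absent from one side of the validation split; "
                "a larger cohort is needed"
            )
    return (
        cohort.replace(cohort.data.iloc[train_idx]),
        cohort.replace(cohort.data.iloc[val_idx]),
    )


def check_stopping(ledger: TrainingLedger, config: CyclicalConfig) -> StopDecision:
    """Iteration cap, or validation plateau at every center simultaneously."""
    if ledger.iteration_count >= config.max_iterations:
        return StopDecision(True, "max_iterations")
    if ledger.centers and all(
        ledger.cycles_since_improvement[c] >= config.patience for c in ledger.centers
    ):
        return StopDecision(True, "dual_plateau")
    return StopDecision(False, None)


def _log_loss(y: np.ndarray, p: np.ndarray) -> float:
    """Class-balanced validation cross-entropy.

    Both imbalance strategies train toward the balanced objective, so the
    plateau detector must watch the balanced loss too: under the raw
    (prevalence-weighted) loss, early balanced training *increases*
    validation loss while predictions move away from the base rate, and
    the strict-improvement counter would declare a plateau long before
    convergence.
    """
    p = np.clip(p, 1e-12, 1 - 1e-12)
    w = np.where(y == 1, len(y) / (2 * max((y == 1).sum(), 1)),
                 len(y) / (2 * max((y == 0).sum(), 1)))
    return float(-np.mean(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


def cwt_train(
    cohorts: Mapping[str, CohortTable],
    kind: str,
    imbalance: str = "class_weighting",
    config: CyclicalConfig | None = None,
    hyperparams: Mapping | None = None,
) -> tuple[L.ExchangeableModel, TrainingLedger]:
    """Run the cyclical protocol over (already imputed) per-center cohorts.

    Returns the final model — whose provenance alternates center ids — and
    the training ledger. With a single center the protocol degenerates to
    plain repeated local training under the same stopping budget.
    """
    config = config or CyclicalConfig()
    if imbalance not in ("class_weighting", "random_oversampling"):
        raise ContractError(f"unknown imbalance strategy {imbalance!r}")
    ordered = order_centers(cohorts)
    if not ordered:
        raise ContractError("at least one center is required")
    for cid in ordered:
        y = cohorts[cid].outcomes().to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise DegenerateDataError(f"center {cid} holds a single outcome class")

    # Per-center local workspaces, built before any exchange. Oversampling is
    # drawn once per center so the cyclical objective is stable across visits.
    work: dict[str, dict] = {}
    for i, cid in enumerate(ordered):
        train, val = split_validation(
            cohorts[cid], config.validation_fraction, config.seed + i
        )
        ws: dict = {"y_val": val.outcomes().to_numpy(dtype=int)}
        fit_part = train
        weights = None
        if imbalance == "random_oversampling":
            fit_part = random_oversample(train, config.seed + i)
        else:
            weights = sample_weights(train.outcomes())
        ws["y_fit"] = fit_part.outcomes().to_numpy(dtype=int)
        ws["weights"] = weights
        if kind in L.NN_KINDS:
            scaler = fit_scaler(train)
            ws["scaler"] = scaler
            ws["X_fit"] = apply_scaler(scaler, fit_part)
            ws["X_val"] = apply_scaler(scaler, val)
        else:
            ws["X_fit"] = encode_for_trees(fit_part)
            ws["X_val"] = encode_for_trees(val)
        work[cid] = ws

    hp = dict(hyperparams or {})
    if kind in L.NN_KINDS:
        hp["n_features"] = work[ordered[0]]["X_fit"].shape[1]
    model = L.init_model(kind, hp, config.seed)
    ledger = TrainingLedger(centers=list(ordered))

    pos = 0
    while True:
        cid = ordered[pos % len(ordered)]
        ws = work[cid]
        if kind in L.NN_KINDS:
            model = L.nn_update(
                model, ws["X_fit"], ws["y_fit"], ws["weights"],
                epochs=config.epochs_per_cycle, center_id=cid,
            )
        else:
            model = L.extend_trees(
                model, ws["X_fit"], ws["y_fit"], ws["weights"],
                k=config.trees_per_cycle, center_id=cid,
            )
        loss = _log_loss(ws["y_val"], L.predict_proba(model, ws["X_val"]))
        ledger.record(cid, loss)
        decision = check_stopping(ledger, config)
        if decision.stop:
            ledger.stop_reason = decision.reason
            break
        pos += 1
        if ordered[pos % len(ordered)] != cid:
            # hand-over: the serialized envelope is the only thing that moves
            model = L.deserialize(L.serialize(model))
    return model, ledger
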