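"""Combined local models: per-center training, one exchange, a 2-feature meta-fit.

Each center tunes and fits its own model on its own data (grid search with
stratified 5-fold cross-validation), then the fitted models and the
probability outputs for the training rows are exchanged across the
boundary exactly once. A logistic regression is trained on the pooled
training rows represented by just two features — the probability assigned
by center A's model and by center B's model — and the stack predicts by
passing the two local probabilities through that logistic map. Models of
different kinds are never stacked together.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import learners as L
from .errors import ContractError, DegenerateDataError
from .synthetic_cohort import CohortTable

__all__ = [
    "ChannelLog",
    "StackedModel",
    "grid_search_local",
    "compute_probability_features",
    "fit_meta",
    "stacked_predict",
    "train_stacked",
]


@dataclass
class ChannelLog:
    """Transcript of everything that crossed the inter-center boundary."""

    transfers: list[dict] = field(default_factory=list)

    def send(self, artifact: str, sender: str) -> None:
        self.transfers.append({"artifact": artifact, "from": sender})

    def count(self, artifact: str, sender: str | None = None) -> int:
        return sum(
            1
            for t in self.transfers
            if t["artifact"] == artifact and (sender is None or t["from"] == sender)
        )


@dataclass
class StackedModel:
    """Two same-kind local models joined by a 2-feature logistic meta-learner.

    ``center_order`` fixes the meta-feature order; ``meta_coefficients[i]``
    weighs the probability produced by ``local_models[center_order[i]]``.
    """

    local_models: dict[str, L.FittedLocalModel]
    center_order: tuple[str, str]
    meta_intercept: float
    meta_coefficients: np.ndarray
    meta_used_ridge: bool = False

    def __post_init__(self) -> None:
        if len(self.local_models) != 2 or len(self.meta_coefficients) != 2:
            raise ContractError("a stacked model combines exactly two centers")
        kinds = {m.model.kind for m in self.local_models.values()}
        if len(kinds) != 1:
            raise ContractError(f"local models must share one kind, got {kinds}")


def grid_search_local(
    cohort: CohortTable,
    kind: str,
    grid: Mapping[str, Sequence] | None = None,
    imbalance: str = "class_weighting",
    seed: int = 0,
    cv: int = 5,
) -> L.FittedLocalModel:
    """Tune one center's model by mean AUC over a stratified ``cv``-fold split.

    Grid points are scored in declared order and ties keep the first; the
    winner is refit on the full partition. A single-point grid skips the
    inner cross-validation and fits directly.
    """
    from sklearn.model_selection import StratifiedKFold

    if grid is None:
        grid = L.DEFAULT_GRID[kind]
    names = list(grid)
    combos = [dict(zip(names, vals)) for vals in itertools.product(*(grid[n] for n in names))]
    if not combos or any(len(grid[n]) == 0 for n in names):
        raise ContractError("hyperparameter grid is empty")
    if len(combos) == 1:
        return L.fit_local(cohort, kind, combos[0], imbalance, seed)

    from .evaluation import auc  # local import: evaluation builds on this module

    y = cohort.outcomes().to_numpy(dtype=int)
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    best_score, best_hp = -np.inf, None
    folds = list(splitter.split(np.zeros(len(y)), y))
    for hp in combos:
        scores = []
        for train_idx, val_idx in folds:
            train = cohort.replace(cohort.data.iloc[train_idx])
            val = cohort.replace(cohort.data.iloc[val_idx])
            fitted = L.fit_local(train, kind, hp, imbalance, seed)
            scores.append(auc(fitted.predict_proba(val), val.outcomes()))
        score = float(np.mean(scores))
        if score > best_score:  # strict: ties keep the earlier grid point
            best_score, best_hp = score, hp
    return L.fit_local(cohort, kind, best_hp, imbalance, seed)


def compute_probability_features(
    local_models: Mapping[str, L.FittedLocalModel],
    cohort: CohortTable,
    center_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score every row of ``cohort`` with each center's model.

    One column per local model, in ``center_order`` (default: sorted center
    ids), aligned to the cohort's row index.
    """
    order = list(center_order) if center_order is not None else sorted(local_models)
    cols = {}
    for cid in order:
        fitted = local_models[cid]
        if fitted.model.n_components == 0:
            raise ContractError(f"local model of center {cid} is unfitted")
        cols[f"prob_{cid}"] = fitted.predict_proba(cohort)
    return pd.DataFrame(cols, index=cohort.data.index)


def fit_meta(
    prob_features, outcomes
) -> tuple[float, np.ndarray, bool]:
    """Maximum-likelihood logistic fit of outcome on the probability features.

    Returns ``(intercept, coefficients, used_ridge)``. When the fit is not
    identifiable (rank-deficient design, e.g. constant probability columns)
    or the unpenalized likelihood has no finite maximizer (perfect
    separation), a ridge-stabilized fit (penalty 1e-6) is used instead and
    flagged.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    F = np.asarray(prob_features, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("meta fit needs both outcome classes")

    # identifiable column subset: greedily keep columns that are not linear
    # combinations of the intercept and columns already kept; redundant
    # directions (e.g. a constant probability column) get coefficient 0.
    keep: list[int] = []
    basis = [np.ones(len(F))]
    for j in range(F.shape[1]):
        candidate = np.column_stack(basis + [F[:, j]])
        if np.linalg.matrix_rank(candidate) == len(basis) + 1:
            keep.append(j)
            basis.append(F[:, j])
    coefs = np.zeros(F.shape[1])
    if not keep:  # no informative direction: closed-form intercept-only fit
        rate = y.mean()
        return float(np.log(rate / (1 - rate))), coefs, False

    F_kept = F[:, keep]
    used_ridge = False
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10_000)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(F_kept, y)
            ok = np.all(np.isfinite(clf.coef_[0])) and np.abs(clf.coef_[0]).max() < 1e4
        except ConvergenceWarning:
            ok = False
    if not ok:
        clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=10_000)
        clf.fit(F_kept, y)
        used_ridge = True
    coefs[keep] = clf.coef_[0]
    return float(clf.intercept_[0]), coefs, used_ridge


def stacked_predict(stacked: StackedModel, cohort: CohortTable) -> np.ndarray:
    """logistic(intercept + coefficients . local probabilities), per row."""
    F = compute_probability_features(
        stacked.local_models, cohort, stacked.center_order
    ).to_numpy()
    return expit(stacked.meta_intercept + F @ stacked.meta_coefficients)


def train_stacked(
    cohorts: Mapping[str, CohortTable],
    kind: str,
    grid: Mapping[str, Sequence] | None = None,
    imbalance: str = "class_weighting",
    seed: int = 0,
    channel: ChannelLog | None = None,
) -> StackedModel:
    """Full stacking protocol over two centers' training partitions.

    Local models are tuned and fit strictly within their center; each
    center then ships its serialized model and its training-row probability
    table across the channel once, and the pooled probability rows train
    the 2-feature logistic meta-learner.
    """
    if len(cohorts) != 2:
        raise ContractError("stacking is defined over exactly two centers")
    channel = channel if channel is not None else ChannelLog()
    order = tuple(sorted(cohorts))
    local: dict[str, L.FittedLocalModel] = {}
    for cid in order:
        fitted = grid_search_local(cohorts[cid], kind, grid, imbalance, seed)
        # the model crosses the boundary as an envelope, exactly once
        fitted = L.FittedLocalModel(
            model=L.deserialize(L.serialize(fitted.model)), scaler=fitted.scaler
        )
        channel.send("model", cid)
        local[cid] = fitted
    frames, ys = [], []
    for cid in order:
        probs = compute_probability_features(local, cohorts[cid], order)
        channel.send("probability_table", cid)
        frames.append(probs)
        ys.append(cohorts[cid].outcomes().to_numpy(dtype=int))
    intercept, coefs, used_ridge = fit_meta(
        pd.concat(frames).to_numpy(), np.concatenate(ys)
    )
    return StackedModel(
        local_models=local,
        center_order=order,
        meta_intercept=intercept,
        meta_coefficients=coefs,
        meta_used_ridge=used_ridge,
    )
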