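"""Evaluation protocol: per-center stratified k-fold AUC over three regimes.

Each center splits its own rows into k stratified folds (default 20). Fold
i of every center is held out in iteration i; the remaining rows form the
training partitions on which the regime under test — mono-center
baseline, cyclical weight transfer, or stacking — builds its model(s).
All preprocessing statistics (imputation, and standardization for the
networks) are fitted on training rows of the owning center only. The same
fold assignment is reused for every (regime, learner, imbalance) cell, so
the 30-cell experiment matrix compares regimes on identical test folds.

AUC is the rank statistic P(score_pos > score_neg) + 0.5 P(tie); per cell
the mean and sample standard deviation over the k fold AUCs are reported
per center, plus the average of the two center means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import learners as L
from .cyclical_training import CyclicalConfig, cwt_train
from .errors import ContractError, DegenerateDataError
from .preprocessing import (
    IMBALANCE_STRATEGIES,
    apply_imputer,
    apply_scaler,
    encode_for_trees,
    fit_imputer,
    fit_scaler,
)
from .stacking import grid_search_local, stacked_predict, train_stacked
from .synthetic_cohort import CohortTable

__all__ = [
    "FoldAssignment",
    "RegimeResult",
    "ExperimentReport",
    "EvalConfig",
    "REGIMES",
    "stratified_kfold",
    "auc",
    "roc_points",
    "run_regime",
    "run_experiment_matrix",
]

REGIMES = ("cyclical", "stacking", "mono_center")


@dataclass
class FoldAssignment:
    """Fold index per row of one center's cohort."""

    folds: np.ndarray
    k: int
    seed: int


def stratified_kfold(outcomes: Sequence[int], k: int, seed: int) -> FoldAssignment:
    """Outcome-stratified fold assignment: sizes and per-fold positives differ by <=1."""
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(outcomes, dtype=int)
    if k < 2:
        raise ContractError("k must be >= 2")
    if len(y) < k:
        raise ContractError(f"need at least {k} rows for {k} folds, got {len(y)}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fewer positives than folds is acceptable
        for i, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
            folds[test_idx] = i
    return FoldAssignment(folds=folds, k=k, seed=seed)


def auc(scores, labels) -> float:
    """ROC AUC in its Mann-Whitney form; undefined (error) for one-class labels."""
    from sklearn.metrics import roc_auc_score

    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("AUC undefined with a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC coordinates (fpr, tpr, threshold) for plotting/export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(np.asarray(labels, int), np.asarray(scores, float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class RegimeResult:
    """One cell of the experiment matrix: k fold AUCs per center."""

    regime: str
    kind: str
    imbalance: str
    fold_aucs: dict[str, list[float]]
    pooled_scores: dict[str, np.ndarray] = field(default_factory=dict)
    pooled_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def center_mean(self, cid: str) -> float:
        return float(np.nanmean(self.fold_aucs[cid]))

    def center_std(self, cid: str) -> float:
        vals = np.asarray(self.fold_aucs[cid], dtype=float)
        vals = vals[~np.isnan(vals)]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")

    @property
    def average_of_centers(self) -> float:
        return float(np.mean([self.center_mean(c) for c in sorted(self.fold_aucs)]))


@dataclass
class EvalConfig:
    """Configuration of the full experiment matrix."""

    k: int = 20
    seed: int = 0
    regimes: tuple = REGIMES
    kinds: tuple = L.LEARNER_KINDS
    imbalances: tuple = IMBALANCE_STRATEGIES
    cyclical: CyclicalConfig = field(default_factory=CyclicalConfig)
    #: per-kind grid for mono/stacking local searches (None -> package default)
    grids: dict | None = None
    #: per-kind fixed hyperparameters for cyclical updates and reused searches
    hyperparams: dict | None = None
    #: skip per-fold grid search and fit mono/stacking locals at `hyperparams`
    reuse_search: bool = False

    @classmethod
    def from_yaml(cls, path) -> "EvalConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cyc = CyclicalConfig(**raw.pop("cyclical", {}))
        known = {f for f in cls.__dataclass_fields__} - {"cyclical"}
        unknown = set(raw) - known
        if unknown:
            raise ContractError(f"unknown config key(s): {sorted(unknown)}")
        return cls(cyclical=cyc, **{k: v for k, v in raw.items()})

    def grid_for(self, kind: str):
        if self.grids and kind in self.grids:
            return self.grids[kind]
        return L.DEFAULT_GRID[kind]

    def hyperparams_for(self, kind: str):
        if self.hyperparams and kind in self.hyperparams:
            return self.hyperparams[kind]
        return None


def _fold_seed(seed: int, i: int) -> int:
    return (seed * 100_003 + 7919 * i) % (2**31 - 1)


def _safe_auc(scores, labels, context: str) -> float:
    try:
        return auc(scores, labels)
    except DegenerateDataError:
        warnings.warn(f"{context}: single-class test fold, AUC recorded as missing")
        return float("nan")


def run_regime(
    cohorts: Mapping[str, CohortTable],
    regime: str,
    kind: str,
    imbalance: str,
    folds: Mapping[str, FoldAssignment],
    config: EvalConfig | None = None,
) -> RegimeResult:
    """Evaluate one (regime, learner, imbalance) cell over the shared folds."""
    config = config or EvalConfig()
    if regime not in REGIMES:
        raise ContractError(f"unknown regime {regime!r}")
    cids = sorted(cohorts)
    k = folds[cids[0]].k
    fold_aucs: dict[str, list[float]] = {c: [] for c in cids}
    pooled_s: dict[str, list[np.ndarray]] = {c: [] for c in cids}
    pooled_y: dict[str, list[np.ndarray]] = {c: [] for c in cids}

    for i in range(k):
        fseed = _fold_seed(config.seed, i)
        trains: dict[str, CohortTable] = {}
        tests: dict[str, CohortTable] = {}
        for cid in cids:
            mask = folds[cid].folds == i
            train = cohorts[cid].replace(cohorts[cid].data.loc[~mask])
            test = cohorts[cid].replace(cohorts[cid].data.loc[mask])
            imputer = fit_imputer(train)
            trains[cid] = apply_imputer(imputer, train)
            tests[cid] = apply_imputer(imputer, test)

        scores: dict[str, np.ndarray] = {}
        if regime == "mono_center":
            for cid in cids:
                if config.reuse_search:
                    fitted = L.fit_local(
                        trains[cid], kind, config.hyperparams_for(kind), imbalance, fseed
                    )
                else:
                    fitted = grid_search_local(
                        trains[cid], kind, config.grid_for(kind), imbalance, fseed
                    )
                scores[cid] = fitted.predict_proba(tests[cid])
        elif regime == "stacking":
            if config.reuse_search:
                hp = config.hyperparams_for(kind) or L.DEFAULT_HYPERPARAMS[kind]
                grid = {name: [value] for name, value in hp.items()}
            else:
                grid = config.grid_for(kind)
            stacked = train_stacked(trains, kind, grid, imbalance, fseed)
            for cid in cids:
                scores[cid] = stacked_predict(stacked, tests[cid])
        else:  # cyclical
            cyc = CyclicalConfig(**{**asdict(config.cyclical), "seed": fseed})
            model, _ = cwt_train(
                trains, kind, imbalance, cyc, config.hyperparams_for(kind)
            )
            for cid in cids:
                if kind in L.NN_KINDS:
                    scaler = fit_scaler(trains[cid])
                    X_test = apply_scaler(scaler, tests[cid])
                else:
                    X_test = encode_for_trees(tests[cid])
                scores[cid] = L.predict_proba(model, X_test)

        for cid in cids:
            y_test = tests[cid].outcomes().to_numpy(dtype=int)
            fold_aucs[cid].append(
                _safe_auc(scores[cid], y_test, f"{regime}/{kind}/{imbalance} fold {i} {cid}")
            )
            pooled_s[cid].append(np.asarray(scores[cid], float))
            pooled_y[cid].append(y_test)

    return RegimeResult(
        regime=regime,
        kind=kind,
        imbalance=imbalance,
        fold_aucs=fold_aucs,
        pooled_scores={c: np.concatenate(pooled_s[c]) for c in cids},
        pooled_labels={c: np.concatenate(pooled_y[c]) for c in cids},
    )


@dataclass
class ExperimentReport:
    """regime x learner x imbalance grid of per-center AUC mean +/- std."""

    results: list[RegimeResult]
    config: EvalConfig
    errors: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        triples = [(r.regime, r.kind, r.imbalance) for r in self.results]
        if len(set(triples)) != len(triples):
            raise ContractError("duplicated (regime, kind, imbalance) cell")

    def get(self, regime: str, kind: str, imbalance: str) -> RegimeResult:
        for r in self.results:
            if (r.regime, r.kind, r.imbalance) == (regime, kind, imbalance):
                return r
        raise KeyError((regime, kind, imbalance))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            cids = sorted(r.fold_aucs)
            row = {"regime": r.regime, "model": r.kind, "strategy": r.imbalance}
            for cid in cids:
                row[f"center{cid}_mean"] = r.center_mean(cid)
                row[f"center{cid}_std"] = r.center_std(cid)
            row["average_of_centers"] = r.average_of_centers
            rows.append(row)
        return pd.DataFrame(rows)

    def fold_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            for cid, aucs in sorted(r.fold_aucs.items()):
                for i, a in enumerate(aucs):
                    rows.append(
                        {
                            "regime": r.regime,
                            "model": r.kind,
                            "strategy": r.imbalance,
                            "center": cid,
                            "fold": i,
                            "auc": a,
                        }
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary_frame().to_csv(path, index=False)

    def to_text(self) -> str:
        """Aligned text table; per-column maxima are flagged with '*'."""
        df = self.summary_frame()
        cids = sorted(self.results[0].fold_aucs) if self.results else []
        value_cols = [f"center{c}" for c in cids] + ["average"]
        header = f"{'regime':<12} {'model':<16} {'strategy':<20}"
        for vc in value_cols:
            header += f" {vc:>15}"
        lines = [header, "-" * len(header)]
        maxima = {}
        for vc, col in zip(
            value_cols, [f"center{c}_mean" for c in cids] + ["average_of_centers"]
        ):
            maxima[vc] = df[col].max()
        for _, row in df.iterrows():
            line = f"{row['regime']:<12} {row['model']:<16} {row['strategy']:<20}"
            for vc, (mcol, scol) in zip(
                value_cols,
                [(f"center{c}_mean", f"center{c}_std") for c in cids]
                + [("average_of_centers", None)],
            ):
                mark = "*" if row[mcol] == maxima[vc] else " "
                if scol is not None:
                    cell = f"{row[mcol]:.2f} +/- {row[scol]:.2f}{mark}"
                else:
                    cell = f"{row[mcol]:.2f}{mark}"
                line += f" {cell:>15}"
            lines.append(line)
        return "\n".join(lines)


def run_experiment_matrix(
    cohorts: Mapping[str, CohortTable], config: EvalConfig | None = None
) -> ExperimentReport:
    """Every regime x learner x imbalance cell on one shared fold assignment.

    Failing cells are recorded (regime, kind, imbalance, error) and the
    report is returned with the cells that completed.
    """
    config = config or EvalConfig()
    folds = {
        cid: stratified_kfold(cohorts[cid].outcomes(), config.k, config.seed)
        for cid in sorted(cohorts)
    }
    results: list[RegimeResult] = []
    errors: list[dict] = []
    for regime in config.regimes:
        for kind in config.kinds:
            for imbalance in config.imbalances:
                try:
                    results.append(
                        run_regime(cohorts, regime, kind, imbalance, folds, config)
                    )
                except Exception as exc:  # partial reports are better than none
                    errors.append(
                        {
                            "regime": regime,
                            "kind": kind,
                            "imbalance": imbalance,
                            "error": repr(exc),
                        }
                    )
    return ExperimentReport(results=results, config=config, errors=errors)
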