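"""Synthetic two-center cohort generation.

Real multi-hospital cohorts for post-procedural mortality modelling are
rarely shareable, but their published baseline-characteristics tables are:
per-center, per-outcome-stratum summaries (mean +/- sd for continuous
variables, category counts for categorical ones). This module turns such a
table into a generative model — sample the outcome stratum, then draw each
feature independently from the stratum's marginal — so that the full
distributed-training pipeline can be exercised end to end without any
patient-level data.

Two generators are provided:

* :func:`generate_center_population` — matches a published table exactly in
  outcome counts and, in expectation, in every stratum marginal, including
  structured missingness (category counts that undershoot the stratum size
  leave the residual missing).
* :func:`generate_logistic_cohorts` — a parametric logistic-model generator
  with per-center covariate shift, for parameter-recovery and
  "does combined training beat the small center alone" experiments where
  the true risk model must be known.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

from .errors import FormatError, SpecValidationError

__all__ = [
    "VariableSpec",
    "StratumSummary",
    "CenterDistributionSpec",
    "CohortTable",
    "build_default_specs",
    "load_specs",
    "dump_specs",
    "generate_center_population",
    "generate_logistic_cohorts",
    "calibrate_intercept",
    "write_cohort",
    "read_cohort",
]

OUTCOME_COL = "outcome"
CENTER_COL = "center"
ID_COL = "patient_id"

#: half-width of the truncation window for continuous draws, in sd units
TRUNCATION_SDS = 5.0


@dataclass(frozen=True)
class VariableSpec:
    """One clinical variable: a continuous measurement or a coded category."""

    name: str
    kind: str  # "continuous" | "categorical"
    units: str = ""
    categories: tuple[str, ...] = ()
    #: continuous quantities that cannot be negative are truncated at zero
    nonnegative: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SpecValidationError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "categorical" and len(self.categories) < 2:
            raise SpecValidationError(f"{self.name}: categorical needs >=2 categories")
        if self.kind == "continuous" and self.categories:
            raise SpecValidationError(f"{self.name}: continuous variable has categories")


@dataclass(frozen=True)
class StratumSummary:
    """Marginal summary of one variable within one outcome stratum."""

    variable: str
    mean: float | None = None
    sd: float | None = None
    category_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        has_moments = self.mean is not None or self.sd is not None
        has_counts = self.category_counts is not None
        if has_moments == has_counts:
            raise SpecValidationError(
                f"{self.variable}: exactly one of mean/sd or category_counts required"
            )
        if has_moments and (self.mean is None or self.sd is None or self.sd < 0):
            raise SpecValidationError(f"{self.variable}: need mean and sd >= 0")
        if has_counts and any(c < 0 for c in self.category_counts.values()):
            raise SpecValidationError(f"{self.variable}: negative category count")


@dataclass(frozen=True)
class CenterDistributionSpec:
    """Everything needed to simulate one center's cohort.

    ``survived_summaries`` / ``died_summaries`` hold one
    :class:`StratumSummary` per schema variable, keyed implicitly by
    ``StratumSummary.variable``.
    """

    center_id: str
    n_survived: int
    n_died: int
    schema: tuple[VariableSpec, ...]
    survived_summaries: tuple[StratumSummary, ...]
    died_summaries: tuple[StratumSummary, ...]

    def __post_init__(self) -> None:
        if self.n_survived < 0 or self.n_died < 0:
            raise SpecValidationError("stratum sizes must be nonnegative")
        names = [v.name for v in self.schema]
        if len(set(names)) != len(names):
            raise SpecValidationError("duplicate variable names in schema")
        for stratum_name, summaries, size in (
            ("survived", self.survived_summaries, self.n_survived),
            ("died", self.died_summaries, self.n_died),
        ):
            by_var = {s.variable: s for s in summaries}
            if set(by_var) != set(names):
                raise SpecValidationError(
                    f"{self.center_id}/{stratum_name}: summaries do not cover schema"
                )
            for var in self.schema:
                s = by_var[var.name]
                if var.kind == "continuous" and s.category_counts is not None:
                    raise SpecValidationError(f"{var.name}: counts given for continuous")
                if var.kind == "categorical":
                    if s.category_counts is None:
                        raise SpecValidationError(f"{var.name}: counts missing")
                    unknown = set(s.category_counts) - set(var.categories)
                    if unknown:
                        raise SpecValidationError(f"{var.name}: unknown categories {unknown}")
                    if size and sum(s.category_counts.values()) > size:
                        raise SpecValidationError(
                            f"{self.center_id}/{stratum_name}/{var.name}: "
                            "category counts exceed stratum size"
                        )

    @property
    def n_total(self) -> int:
        return self.n_survived + self.n_died

    def summary(self, stratum: str, variable: str) -> StratumSummary:
        pool = self.survived_summaries if stratum == "survived" else self.died_summaries
        for s in pool:
            if s.variable == variable:
                return s
        raise KeyError(variable)


@dataclass
class CohortTable:
    """Per-patient feature rows plus a binary one-year-mortality outcome.

    ``data`` holds one column per schema variable plus ``outcome`` (0/1,
    never missing in an accepted cohort); the index carries patient ids.
    ``oversampled`` marks tables where duplicated ids are expected.
    """

    data: pd.DataFrame
    schema: tuple[VariableSpec, ...]
    center_id: str
    oversampled: bool = False

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return [v.name for v in self.schema]

    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    def outcomes(self) -> pd.Series:
        return self.data[OUTCOME_COL]

    def validate(self) -> None:
        if not self.oversampled and self.data.index.has_duplicates:
            raise SpecValidationError("duplicate patient ids in non-oversampled cohort")
        if self.data[OUTCOME_COL].isna().any():
            raise SpecValidationError("missing outcome in accepted cohort")
        for var in self.schema:
            if var.kind == "categorical":
                observed = self.data[var.name].dropna()
                bad = set(observed.unique()) - set(var.categories)
                if bad:
                    raise SpecValidationError(f"{var.name}: values outside categories {bad}")

    def replace(self, data: pd.DataFrame, oversampled: bool | None = None) -> "CohortTable":
        return CohortTable(
            data=data,
            schema=self.schema,
            center_id=self.center_id,
            oversampled=self.oversampled if oversampled is None else oversampled,
        )


# ---------------------------------------------------------------------------
# spec (de)serialization


def _schema_from_yaml(raw: Sequence[Mapping]) -> tuple[VariableSpec, ...]:
    out = []
    for entry in raw:
        out.append(
            VariableSpec(
                name=str(entry["name"]),
                kind=str(entry["kind"]),
                units=str(entry.get("units", "")),
                categories=tuple(str(c) for c in entry.get("categories", ())),
                nonnegative=bool(entry.get("nonnegative", True)),
            )
        )
    return tuple(out)


def _summaries_from_yaml(
    raw: Mapping[str, Mapping], schema: Sequence[VariableSpec]
) -> tuple[StratumSummary, ...]:
    out = []
    for var in schema:
        cell = raw[var.name]
        if var.kind == "continuous":
            out.append(StratumSummary(var.name, mean=float(cell["mean"]), sd=float(cell["sd"])))
        else:
            out.append(
                StratumSummary(
                    var.name,
                    category_counts={str(k): int(v) for k, v in cell.items()},
                )
            )
    return tuple(out)


def load_specs(source) -> dict[str, CenterDistributionSpec]:
    """Parse a YAML distribution spec (path or file object) into per-center specs."""
    if hasattr(source, "read"):
        raw = yaml.safe_load(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    schema = _schema_from_yaml(raw["schema"])
    specs = {}
    for center_id, block in raw["centers"].items():
        specs[str(center_id)] = CenterDistributionSpec(
            center_id=str(center_id),
            n_survived=int(block["n_survived"]),
            n_died=int(block["n_died"]),
            schema=schema,
            survived_summaries=_summaries_from_yaml(block["survived"], schema),
            died_summaries=_summaries_from_yaml(block["died"], schema),
        )
    return specs


def dump_specs(specs: Mapping[str, CenterDistributionSpec], path) -> None:
    """Write per-center specs back to the YAML layout read by :func:`load_specs`."""
    first = next(iter(specs.values()))
    schema_block = []
    for v in first.schema:
        entry: dict = {"name": v.name, "kind": v.kind, "units": v.units}
        if v.categories:
            entry["categories"] = list(v.categories)
        if not v.nonnegative:
            entry["nonnegative"] = False
        schema_block.append(entry)
    centers = {}
    for cid, spec in specs.items():
        def stratum(summaries):
            block = {}
            for s in summaries:
                if s.category_counts is not None:
                    block[s.variable] = dict(s.category_counts)
                else:
                    block[s.variable] = {"mean": s.mean, "sd": s.sd}
            return block

        centers[cid] = {
            "n_survived": spec.n_survived,
            "n_died": spec.n_died,
            "survived": stratum(spec.survived_summaries),
            "died": stratum(spec.died_summaries),
        }
    with open(path, "w") as fh:
        yaml.safe_dump({"schema": schema_block, "centers": centers}, fh, sort_keys=False)


def build_default_specs() -> tuple[CenterDistributionSpec, CenterDistributionSpec]:
    """Packaged default: the two-center TAVI baseline table (A: 1160, B: 631)."""
    ref = importlib.resources.files("fedcohort.data").joinpath("table1.yaml")
    with ref.open() as fh:
        specs = load_specs(fh)
    return specs["A"], specs["B"]


# ---------------------------------------------------------------------------
# generation


def _draw_continuous(
    rng: np.random.Generator, summary: StratumSummary, var: VariableSpec, n: int
) -> np.ndarray:
    mean, sd = float(summary.mean), float(summary.sd)
    if n == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(n, mean)
    lo = mean - TRUNCATION_SDS * sd
    if var.nonnegative:
        lo = max(lo, 0.0)
    hi = mean + TRUNCATION_SDS * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _draw_categorical(
    rng: np.random.Generator, summary: StratumSummary, var: VariableSpec, n: int
) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=object)
    counts = np.array([summary.category_counts.get(c, 0) for c in var.categories], float)
    residual = n - counts.sum()  # unreported rows of the stratum -> missing
    labels = list(var.categories) + [None]
    p = np.append(counts, residual) / n
    idx = rng.choice(len(labels), size=n, p=p)
    return np.array([labels[i] for i in idx], dtype=object)


def generate_center_population(spec: CenterDistributionSpec, seed: int) -> CohortTable:
    """Simulate one center's cohort conditionally on the outcome stratum.

    Exactly ``n_survived`` rows get outcome 0 and ``n_died`` outcome 1;
    features are drawn independently per stratum — truncated normal for
    continuous variables, the count-implied multinomial (with the residual
    mass as missing) for categorical ones. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for stratum, n, outcome in (
        ("survived", spec.n_survived, 0),
        ("died", spec.n_died, 1),
    ):
        cols: dict[str, np.ndarray] = {}
        for var in spec.schema:
            s = spec.summary(stratum, var.name)
            if var.kind == "continuous":
                cols[var.name] = _draw_continuous(rng, s, var, n)
            else:
                cols[var.name] = _draw_categorical(rng, s, var, n)
        df = pd.DataFrame(cols, columns=[v.name for v in spec.schema])
        df[OUTCOME_COL] = outcome
        blocks.append(df)
    df = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame()
    if len(df):
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.index = pd.Index(
        [f"{spec.center_id}-{i:05d}" for i in range(len(df))], name=ID_COL
    )
    cohort = CohortTable(data=df, schema=spec.schema, center_id=spec.center_id)
    cohort.validate()
    return cohort


def calibrate_intercept(
    coefficients: Mapping[str, float],
    shift: Mapping[str, float] | float,
    target_rate: float,
) -> float:
    """Intercept for which E[expit(b0 + beta.x)] = target_rate under x ~ N(shift, I).

    The linear predictor is normal with mean sum(beta*shift) and variance
    sum(beta^2); the expectation is integrated numerically (Gauss-Hermite).
    """
    betas = np.array(list(coefficients.values()))
    if isinstance(shift, Mapping):
        mu = sum(coefficients[k] * shift.get(k, 0.0) for k in coefficients)
    else:
        mu = float(shift) * betas.sum()
    sigma = float(np.sqrt((betas**2).sum()))
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)

    def rate(b0: float) -> float:
        return float(weights @ expit(b0 + mu + sigma * nodes) / weights.sum())

    from scipy.optimize import brentq

    return float(brentq(lambda b: rate(b) - target_rate, -30, 30))


def generate_logistic_cohorts(
    coefficients: Mapping[str, float],
    intercepts: tuple[float, float],
    n_per_center: tuple[int, int],
    shift: tuple[Mapping[str, float] | float, Mapping[str, float] | float] = (0.0, 0.0),
    seed: int = 0,
    center_ids: tuple[str, str] = ("A", "B"),
) -> tuple[CohortTable, CohortTable]:
    """Draw two centers from a shared logistic risk model with covariate shift.

    Features are independent unit-variance Gaussians centred at the
    per-center ``shift``; the outcome is Bernoulli(expit(b0_c + beta.x)).
    Feature names are the coefficient keys. Deterministic given ``seed``.
    """
    names = list(coefficients)
    if not names:
        raise SpecValidationError("coefficients must reference at least one variable")
    schema = tuple(VariableSpec(n, "continuous", nonnegative=False) for n in names)
    betas = np.array([coefficients[n] for n in names])
    rng = np.random.default_rng(seed)
    out = []
    for cid, b0, n, sh in zip(center_ids, intercepts, n_per_center, shift):
        if isinstance(sh, Mapping):
            unknown = set(sh) - set(names)
            if unknown:
                raise SpecValidationError(f"shift references unknown variables {unknown}")
            mu = np.array([sh.get(nm, 0.0) for nm in names])
        else:
            mu = np.full(len(names), float(sh))
        X = rng.normal(loc=mu, scale=1.0, size=(n, len(names)))
        p = expit(b0 + X @ betas)
        y = (rng.random(n) < p).astype(int)
        df = pd.DataFrame(X, columns=names)
        df[OUTCOME_COL] = y
        df.index = pd.Index([f"{cid}-{i:05d}" for i in range(n)], name=ID_COL)
        out.append(CohortTable(data=df, schema=schema, center_id=cid))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# CSV round trip


def write_cohort(cohort: CohortTable, path) -> None:
    """CSV with columns patient_id, <variables...>, outcome, center; empty = missing."""
    df = cohort.data.copy()
    df[CENTER_COL] = cohort.center_id
    df.to_csv(path, index=True, index_label=ID_COL, na_rep="")


def read_cohort(path, schema: Sequence[VariableSpec]) -> CohortTable:
    """Read a cohort CSV back against a declared schema.

    Unknown or absent columns raise :class:`FormatError` naming the column;
    empty fields become missing values.
    """
    schema = tuple(schema)
    df = pd.read_csv(path, index_col=ID_COL, dtype={v.name: object for v in schema
                                                    if v.kind == "categorical"})
    expected = {v.name for v in schema} | {OUTCOME_COL, CENTER_COL}
    unknown = set(df.columns) - expected
    if unknown:
        raise FormatError(f"unknown column(s) in cohort file: {sorted(unknown)}")
    missing = expected - set(df.columns)
    if missing:
        raise FormatError(f"cohort file lacks column(s): {sorted(missing)}")
    centers = df[CENTER_COL].dropna().unique()
    if len(centers) != 1:
        raise FormatError(f"cohort file must contain exactly one center, got {centers}")
    for v in schema:
        if v.kind == "continuous":
            try:
                df[v.name] = pd.to_numeric(df[v.name])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"non-numeric value in column {v.name!r}") from exc
    center_id = str(centers[0])
    data = df.drop(columns=[CENTER_COL])
    cohort = CohortTable(data=data, schema=schema, center_id=center_id)
    cohort.validate()
    return cohort
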