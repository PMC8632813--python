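"""Canned validation experiments for the distributed-training framework.

Real two-hospital cohorts cannot ship with the package, so its claims are
checked on synthetic data three ways:

* structural probes — the default generator reproduces the published
  cohort structure (sizes, outcome counts, shared variables) and the
  protocol constants (2-feature meta-input, iteration cap, network widths);
* equivalence experiments — a cyclically grown forest over two identical
  centers matches an ordinary pooled forest of equal size;
* a directional benchmark — under a known shared logistic risk model with
  per-center covariate shift, both combined regimes (cyclical, stacking)
  should on average beat the small center's mono model on that center's
  held-out folds. This mirrors the qualitative finding the framework
  exists to demonstrate; it is a statement about expectations over many
  simulated worlds, hence the averaging over master seeds.
"""

from __future__ import annotations

import numpy as np

from . import learners as L
from .cyclical_training import CyclicalConfig, cwt_train, split_validation
from .evaluation import EvalConfig, auc, run_regime, stratified_kfold
from .preprocessing import intersect_variables
from .synthetic_cohort import (
    build_default_specs,
    calibrate_intercept,
    generate_center_population,
    generate_logistic_cohorts,
)

__all__ = [
    "default_risk_model",
    "default_cohort_summary",
    "moment_recovery_summary",
    "prevalence_probe",
    "iteration_cap_probe",
    "architecture_probe",
    "meta_width_probe",
    "auc_oracle_agreement",
    "pooled_equivalence",
    "directional_benchmark",
]

#: shared true log-odds coefficients of the parametric benchmark generator
RISK_COEFFICIENTS = {
    "age": 0.9,
    "creatinine": 0.7,
    "nyha": 0.6,
    "copd": 0.5,
    "qrs": -0.4,
    "bmi": -0.35,
    "hemoglobin": -0.3,
    "gradient": 0.25,
    "sex": 0.2,
    "devices": 0.15,
}

#: covariate-mean offsets of the smaller center relative to the larger one
RISK_SHIFT_B = {"age": 0.4, "creatinine": 0.4, "bmi": -0.3}

BENCHMARK_N = (1160, 631)
BENCHMARK_PREVALENCE = 0.10


def default_risk_model() -> dict:
    """Coefficients, shifts and prevalence-calibrated intercepts of the benchmark."""
    b0_a = calibrate_intercept(RISK_COEFFICIENTS, 0.0, BENCHMARK_PREVALENCE)
    b0_b = calibrate_intercept(RISK_COEFFICIENTS, RISK_SHIFT_B, BENCHMARK_PREVALENCE)
    return {
        "coefficients": RISK_COEFFICIENTS,
        "shift": (0.0, RISK_SHIFT_B),
        "intercepts": (b0_a, b0_b),
        "n_per_center": BENCHMARK_N,
    }


def _benchmark_cohorts(seed: int):
    rm = default_risk_model()
    return generate_logistic_cohorts(
        rm["coefficients"], rm["intercepts"], rm["n_per_center"], rm["shift"], seed=seed
    )


# ---------------------------------------------------------------------------
# structural probes


def default_cohort_summary(seed: int) -> dict:
    """Generate both default centers and count what the published table promises."""
    spec_a, spec_b = build_default_specs()
    a = generate_center_population(spec_a, seed)
    b = generate_center_population(spec_b, seed + 1)
    deaths = int(a.outcomes().sum() + b.outcomes().sum())
    total = a.n_rows + b.n_rows
    return {
        "center_a_size": a.n_rows,
        "center_b_size": b.n_rows,
        "center_a_deaths": int(a.outcomes().sum()),
        "center_b_deaths": int(b.outcomes().sum()),
        "total_patients": total,
        "overall_mortality_pct": 100.0 * deaths / total,
        "shared_variables": len(intersect_variables(spec_a.schema, spec_b.schema)),
    }


def moment_recovery_summary(seed: int) -> dict:
    """Worst-case deviation of generated stratum summaries from their targets.

    Deviations are scaled so that 1.0 is the tolerance: 4*sd/sqrt(n) for a
    continuous stratum mean, 4*sqrt(n*p*(1-p)) for a category count.
    """
    worst_cont, worst_cat = 0.0, 0.0
    for offset, spec in enumerate(build_default_specs()):
        cohort = generate_center_population(spec, seed + offset)
        for stratum, outcome, n in (
            ("survived", 0, spec.n_survived),
            ("died", 1, spec.n_died),
        ):
            rows = cohort.data[cohort.data["outcome"] == outcome]
            for var in spec.schema:
                s = spec.summary(stratum, var.name)
                if var.kind == "continuous":
                    if s.sd == 0:
                        continue
                    tol = 4 * s.sd / np.sqrt(n)
                    dev = abs(float(rows[var.name].mean()) - s.mean) / tol
                    worst_cont = max(worst_cont, dev)
                else:
                    counts = rows[var.name].value_counts()
                    for cat, expected in s.category_counts.items():
                        p = expected / n
                        if p in (0.0, 1.0):
                            continue
                        tol = 4 * np.sqrt(n * p * (1 - p))
                        dev = abs(int(counts.get(cat, 0)) - n * p) / tol
                        worst_cat = max(worst_cat, dev)
    return {
        "worst_continuous_mean_deviation": worst_cont,
        "worst_category_count_deviation": worst_cat,
    }


def prevalence_probe(seed: int, n: int = 10_000, intercept: float = -2.197) -> dict:
    """Empirical outcome rate of the null logistic generator (expit(b0) closed form)."""
    coefs = {f"x{i}": 0.0 for i in range(5)}
    a, b = generate_logistic_cohorts(
        coefs, (intercept, intercept), (n, n), (0.0, 0.0), seed=seed
    )
    pooled = np.concatenate([a.outcomes(), b.outcomes()])
    return {
        "empirical_rate": float(pooled.mean()),
        "expected_rate": float(1 / (1 + np.exp(-intercept))),
        "n": 2 * n,
    }


def iteration_cap_probe(seed: int, n: tuple[int, int] = (90, 70)) -> dict:
    """Run the cyclical protocol with plateau stopping disabled; it must hit the cap."""
    coefs = {f"x{i}": c for i, c in enumerate((0.8, -0.5, 0.4))}
    b0 = calibrate_intercept(coefs, 0.0, 0.3)
    a, b = generate_logistic_cohorts(coefs, (b0, b0), n, (0.0, 0.0), seed=seed)
    config = CyclicalConfig(patience=10**6, seed=seed)  # plateau can never fire
    _, ledger = cwt_train({"A": a, "B": b}, "nn_narrow", "class_weighting", config)
    return {
        "iterations": ledger.iteration_count,
        "cap": config.max_iterations,
        "stop_reason": ledger.stop_reason,
    }


def architecture_probe() -> dict:
    """Hidden-layer widths actually instantiated by the two network kinds."""
    out = {}
    for kind in L.NN_KINDS:
        model = L.init_model(kind, {"n_features": 16}, seed=0)
        out[kind] = [w.shape[1] for w in model.state["W"][:-1]]
    return out


def meta_width_probe(seed: int) -> dict:
    """Train a small stack end to end and report the meta-learner's input width."""
    from .stacking import train_stacked

    coefs = {f"x{i}": c for i, c in enumerate((1.0, -0.6))}
    b0 = calibrate_intercept(coefs, 0.0, 0.3)
    a, b = generate_logistic_cohorts(coefs, (b0, b0), (150, 120), (0.0, 0.0), seed=seed)
    stacked = train_stacked(
        {"A": a, "B": b},
        "random_forest",
        grid={"n_estimators": [25]},
        seed=seed,
    )
    return {"meta_features": len(stacked.meta_coefficients)}


def auc_oracle_agreement(seed: int, n_cases: int = 1000, max_rows: int = 12) -> dict:
    """Fraction of random small instances where AUC matches the exhaustive pair count."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        n = int(rng.integers(2, max_rows + 1))
        y = rng.integers(0, 2, size=n)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=n)
        scores = np.round(rng.random(n), 2)  # coarse grid so ties occur
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        oracle = wins / (len(pos) * len(neg))
        if np.isclose(auc(scores, y), oracle, atol=1e-12):
            agree += 1
    return {"agreement": agree / n_cases, "n_cases": n_cases}


# ---------------------------------------------------------------------------
# equivalence and directional experiments


def pooled_equivalence(
    seed: int,
    n_seeds: int = 20,
    n_train: int = 400,
    n_test: int = 800,
    n_trees: int = 50,
) -> dict:
    """Two identical centers, cyclical forest vs an ordinary pooled forest.

    Both forests hold ``n_trees`` trees and train on the same rows (the
    cyclical run's training part); AUC is measured on an independent test
    cohort from the same distribution. Reported is the difference of the
    two mean AUCs across ``n_seeds`` replicates.
    """
    coefs = {f"x{i}": c for i, c in enumerate((0.9, -0.7, 0.5, 0.4, -0.3, 0.2))}
    b0 = calibrate_intercept(coefs, 0.0, 0.2)
    cyc_aucs, pooled_aucs = [], []
    for r in range(n_seeds):
        s = seed + 1000 + r
        train, test = generate_logistic_cohorts(
            coefs, (b0, b0), (n_train, n_test), (0.0, 0.0), seed=s
        )
        copy_a = train.replace(train.data)
        copy_b = train.replace(train.data)
        copy_a.center_id, copy_b.center_id = "A", "B"
        config = CyclicalConfig(
            max_iterations=n_trees, patience=10**6, trees_per_cycle=1, seed=s
        )
        model, _ = cwt_train(
            {"A": copy_a, "B": copy_b}, "random_forest", "class_weighting", config
        )
        from .preprocessing import encode_for_trees

        y_test = test.outcomes().to_numpy(int)
        cyc_aucs.append(auc(L.predict_proba(model, encode_for_trees(test)), y_test))
        # equal-size pooled forest on the same training part as the cyclical run
        fit_part, _ = split_validation(copy_a, config.validation_fraction, config.seed)
        fitted = L.fit_local(
            fit_part, "random_forest", {"n_estimators": n_trees}, "class_weighting", s
        )
        pooled_aucs.append(auc(fitted.predict_proba(test), y_test))
    return {
        "cyclical_mean_auc": float(np.mean(cyc_aucs)),
        "pooled_mean_auc": float(np.mean(pooled_aucs)),
        "abs_gap": float(abs(np.mean(cyc_aucs) - np.mean(pooled_aucs))),
        "n_seeds": n_seeds,
    }


def directional_benchmark(
    seed: int,
    n_seeds: int = 20,
    kinds: tuple[str, ...] = ("random_forest", "nn_narrow"),
    k: int = 5,
) -> dict:
    """Do the combined regimes beat the small center's mono model, on average?

    For each master seed a fresh two-center world is drawn from the shared
    risk model (n = 1160 / 631, ~10% prevalence, covariate shift at the
    smaller center); all three regimes are evaluated on the same stratified
    ``k``-fold assignment with fixed hyperparameters (no per-fold grid
    search — the distributed comparison is the object, not tuning). The
    summary is the mean held-out AUC at the smaller center per regime,
    averaged over seeds and learner kinds.
    """
    per_regime: dict[str, list[float]] = {r: [] for r in ("mono_center", "cyclical", "stacking")}
    per_regime_kind: dict[str, dict[str, list[float]]] = {
        r: {kd: [] for kd in kinds} for r in per_regime
    }
    for r in range(n_seeds):
        s = seed + 10_000 + r
        a, b = _benchmark_cohorts(s)
        cohorts = {"A": a, "B": b}
        folds = {
            cid: stratified_kfold(cohorts[cid].outcomes(), k, s) for cid in cohorts
        }
        for kind in kinds:
            cyc = CyclicalConfig(
                max_iterations=500 if kind in L.NN_KINDS else 100,
                patience=10,
                trees_per_cycle=1,
                epochs_per_cycle=1,
                seed=s,
            )
            config = EvalConfig(k=k, seed=s, cyclical=cyc, reuse_search=True)
            for regime in per_regime:
                result = run_regime(cohorts, regime, kind, "class_weighting", folds, config)
                val = result.center_mean("B")
                per_regime[regime].append(val)
                per_regime_kind[regime][kind].append(val)
    means = {r: float(np.mean(v)) for r, v in per_regime.items()}
    return {
        "small_center_mean_auc": means,
        "by_kind": {
            r: {kd: float(np.mean(v)) for kd, v in kinds_map.items()}
            for r, kinds_map in per_regime_kind.items()
        },
        "gain_cyclical": means["cyclical"] - means["mono_center"],
        "gain_stacking": means["stacking"] - means["mono_center"],
        "n_seeds": n_seeds,
        "k": k,
        "kinds": list(kinds),
    }
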