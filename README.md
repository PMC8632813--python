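# fedcohort

Simulation framework for training clinical prognostic models across two
hospitals **without sharing patient data**, applied to 1-year mortality
prediction after transcatheter aortic valve implantation (TAVI).

Hospitals rarely may pool patient rows, yet single-center models
generalize poorly and small centers lack data. `fedcohort` implements and
compares, under one evaluation protocol, the three regimes available in
that setting:

* **Mono-center** — each center trains and tests on its own cohort (the
  baseline).
* **Cyclical weight transfer (CWT)** — one model travels between the
  centers sequentially and cyclically; each center updates it on local
  data (gradient epochs for neural networks; appending trees for
  forest/boosted ensembles, where trees built elsewhere are never
  modified) until an iteration cap (500) or until the validation loss has
  plateaued at *every* center for 10 consecutive visits.
* **Stacking** — each center tunes and fits its model locally (grid
  search, stratified 5-fold CV); models and probability outputs are
  exchanged once, and a logistic regression on two features — the
  probability from center A's model, p_A(x), and from center B's,
  p_B(x) — produces the combined prediction
  σ(β₀ + β₁ p_A(x) + β₂ p_B(x)).

Five learners sit behind one exchangeable-model contract: random forest,
two gradient-boosted tree variants, and two fully-connected networks
(hidden layers 8/4 and 100/40). Evaluation is stratified 20-fold
cross-validation per center with ROC AUC (Mann–Whitney form) reported as
mean ± sd per center; all regimes share one fold assignment so
comparisons are paired. The only artifacts that ever cross the simulated
center boundary are serialized model envelopes and probability tables —
the channel enforces this by construction, and every tree or update round
records which center produced it.

Because the underlying two-hospital cohorts are private, the package
ships a synthetic generator that reproduces their published
baseline-characteristics table: per-center, per-outcome-stratum means ±
sd and category counts for 16 clinical variables (cohorts of 1,160 and
631 patients, ~10% one-year mortality), including structured missingness
where category counts undershoot the stratum size. A second, parametric
generator draws both centers from a known shared logistic risk model with
per-center covariate shift, for experiments that need ground truth. See
`docs/methods.md` for the modelling details and limitations.

## Worked example

```python
from fedcohort.synthetic_cohort import build_default_specs, generate_center_population
from fedcohort.evaluation import EvalConfig, run_regime, stratified_kfold
from fedcohort.cyclical_training import CyclicalConfig

spec_a, spec_b = build_default_specs()
cohorts = {
    "A": generate_center_population(spec_a, seed=1),
    "B": generate_center_population(spec_b, seed=2),
}
print({cid: (c.n_rows, int(c.outcomes().sum())) for cid, c in cohorts.items()})

config = EvalConfig(
    k=5, seed=0,
    cyclical=CyclicalConfig(max_iterations=100, patience=10),
    hyperparams={"random_forest": {"n_estimators": 100}},
    reuse_search=True,
)
folds = {cid: stratified_kfold(c.outcomes(), config.k, config.seed)
         for cid, c in cohorts.items()}
result = run_regime(cohorts, "cyclical", "random_forest", "class_weighting",
                    folds, config)
for cid in ("A", "B"):
    print(f"center {cid}: AUC {result.center_mean(cid):.3f} "
          f"+/- {result.center_std(cid):.3f}")
```

prints

```
{'A': (1160, 121), 'B': (631, 67)}
center A: AUC 0.695 +/- 0.035
center B: AUC 0.659 +/- 0.082
```

— the generated cohorts match the published sizes and death counts
exactly (1,160 patients with 121 deaths; 631 with 67), and a cyclically
grown 100-tree forest discriminates 1-year mortality on the synthetic
cohorts at AUC ≈ 0.66–0.70 per center over 5 shared test folds.
(Synthetic features are conditionally independent given the outcome, so
these numbers characterize the generator, not the real cohorts; see
`docs/methods.md`.)

The same experiment is available from the shell:

```bash
fedcohort generate --seed 1 --out cohorts/
fedcohort run --regime cyclical --model rf --cohort cohorts/center_A.csv \
              --cohort cohorts/center_B.csv
fedcohort matrix --cohort cohorts/center_A.csv --cohort cohorts/center_B.csv \
                 --out report/   # full 3 regimes x 5 models x 2 strategies grid
```

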