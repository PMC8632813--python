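# Methods

## Problem setting

Two hospitals (center A, n = 1,160; center B, n = 631) each hold a tabular
cohort of patients who underwent transcatheter aortic valve implantation
(TAVI), with 16 shared baseline variables and a binary outcome: death
within one year of the procedure (about 10% overall). Privacy regulation
prevents pooling the rows, so models that want to use both cohorts must
train through restricted channels. The package implements and compares
three regimes under one evaluation protocol:

* **mono-center** — each center trains and tests on its own data only;
* **cyclical weight transfer (CWT)** — one model is passed between the
  centers sequentially and cyclically, each center updating it locally;
* **stacking** — each center trains locally; the fitted models and their
  probability outputs are exchanged once, and a 2-feature logistic
  regression combines the two probability streams.

Only serialized models (CWT) or models plus probability tables (stacking)
cross the center boundary. The exchange channel in this simulation accepts
nothing but the model envelope type, so the constraint is structural, not
a convention.

## Synthetic cohorts

The real cohorts are private; the generator reproduces their published
baseline-characteristics table instead. Generation is conditional on the
outcome stratum: exactly `n_survived` rows with outcome 0 and `n_died`
with outcome 1 per center, then each feature drawn independently from its
stratum marginal —

* continuous variables: truncated normal at the printed mean ± sd, clipped
  at mean ± 5 sd and at 0 for physiologic nonnegative quantities. At these
  sd/mean ratios the truncation removes negligible mass, so stratum means
  and sds are preserved;
* categorical variables: the multinomial implied by the printed counts,
  with the residual mass (counts often undershoot the stratum size, e.g.
  NYHA class) drawn as an explicit missing value. This is the only
  missingness mechanism available from published summaries, and it is what
  exercises the imputation stage.

Conditioning on the outcome bakes the feature–outcome associations implied
by the between-stratum differences into the data without any inverse
modelling, and reproduces the printed summaries exactly in expectation.
What the generator deliberately does **not** model: correlations between
features within a stratum, temporal drift over the enrolment years, and
center-specific missingness beyond the residual-mass reconstruction.
Passing tests on these cohorts therefore demonstrate protocol correctness
and directional behaviour, not clinical-grade effect sizes.

One transcription decision: the source table prints the aortic valve area
of center A non-survivors as "0.8 ± 2". An sd of 2 cm² is physiologically
impossible (valve areas span roughly 0.3–1.2 cm²) and inconsistent with
the 0.2 printed for the other three strata of the same variable; the
packaged spec records 0.2. The Diabetes percentage for center B survivors
is likewise inconsistent with its count; counts are treated as
authoritative throughout.

A second, parametric generator draws two centers from a *known* shared
logistic risk model — independent unit-variance Gaussian features with
per-center mean offsets (covariate shift), outcome Bernoulli at the linear
predictor. Its intercept is calibrated by Gauss–Hermite integration so the
marginal prevalence hits a target (10% in the benchmark) exactly in
expectation. This generator is used wherever ground truth is needed:
prevalence calibration, effect-size monotonicity, and the directional
benchmark.

## Pre-processing

Rows with a missing outcome, or with more than 50% of features missing,
are excluded (a row missing exactly half is retained). Only variables
present in both schemas enter the models. Missing features are imputed
with the column mean (continuous) or mode (categorical); the imputation
statistics are computed per center and a fitted imputer refuses data from
any other center. For the networks, continuous features are standardized
to zero mean and unit variance (population sd, so the unit-variance
statement is exact) and categoricals are one-hot encoded over the full
schema category list — no dropped level, so the encoded width is identical
at both centers even when a category is locally absent. Tree learners
receive integer category codes in schema order instead; they are invariant
to monotone recoding and need no scaling. Class imbalance is handled
inside training partitions only, by either balanced class weights
(w_c = n/(2·n_c), equalizing the weighted class masses) or random
oversampling of the minority class to parity.

In cross-validated evaluation all of these statistics are fitted on
training rows of the owning center only; the held-out fold never
influences them.

## Learners

Five binary classifiers sit behind one exchangeable-model contract:
a random forest, two gradient-boosted tree variants, and two
fully-connected networks (hidden layers 8/4 and 100/40). Tree backends
are scikit-learn (forest), XGBoost and LightGBM; both boosted backends
pin their baseline score to 0.5 (raw score 0) because data-estimated base
scores would make a model's meaning depend on which center initialized
it. The networks are a compact NumPy implementation — ReLU hidden layers,
inverted dropout (default rate 0.2) between them, sigmoid output, weighted
binary cross-entropy, full-batch Adam (default 1e-3) — carrying their own
random stream, optimizer moments and step count in the serialized state,
so an update is bit-reproducible from the envelope alone.

Default tree settings are max_depth 3, learning rate 0.1, and 100 trees
for one-shot local fits; default grids for local tuning are
{max_depth 2/3/4, learning rate 0.05/0.1, trees 50/100/200} for boosting,
{trees 100/300, max_features sqrt/all} for the forest, and
{dropout 0/0.2, epochs 50/200} for the networks. All are conventional
small-tabular choices, surfaced in configuration so better-informed values
can be dropped in.

Contract properties enforced (and tested): appending trees never perturbs
the predictions of any existing prefix; growing a boosted ensemble in two
stages on the same data equals one two-round call; serialization is
prediction-lossless; every tree/update round records which center
produced it, so per-center contribution counts are auditable from the
envelope.

## Cyclical training

The largest center initializes and trains first. Each visit performs one
update block (default: 1 tree, or 1 epoch), measures the *class-balanced*
binary cross-entropy on the center's own validation split, and ships the
envelope onward. The balanced loss (each class weighted inversely to its
validation frequency) is the held-out version of the objective both
imbalance strategies optimize; monitoring the raw, prevalence-weighted
loss instead would declare a plateau spuriously early, because balanced
training first moves predictions away from the base rate and the raw
validation loss *rises* during that phase even as discrimination
improves. The validation split (default 20%) is carved once per
center, stratified by outcome, before the first cycle — a moving
validation set would make "stopped improving" ill-defined. A center is
plateaued after `patience` (default 10) consecutive visits without a
strict improvement of its own validation loss; training stops when **all**
centers are plateaued simultaneously, or at `max_iterations` (default 500)
total center-updates. "Iteration" always means one center-update; it is
the only repeating unit the tree and network families share. Class
weights under CWT use each center's own class frequencies (no shared
statistics), and oversampling is drawn once per center so the local
objective is stable across visits. When stopping fires mid-round the
trailing center simply holds one fewer block of trees; per-center counts
are equal exactly at round boundaries.

At evaluation time each center scores the shared network with its own
standardization statistics (fitted on its training rows). Scales differ
slightly between centers; that asymmetry is inherent to federated
deployment without shared statistics and is accepted here.

## Stacking

Each center tunes its model by grid search with stratified 5-fold
cross-validation on its own training partition (mean AUC; ties keep the
earlier grid point) and refits the winner on the full partition. The
fitted models and the probability outputs for the training rows are
exchanged exactly once. The meta-learner is a logistic regression on the
pooled training rows represented by two features: the probability from
center A's model and from center B's model. Probabilities for a center's
own training rows come from the refit model, not out-of-fold predictions
— the simplest reading of "score all samples", with a known optimism
risk: a strongly overfit local model feeds near-separated features to the
meta-fit. The meta-fit is solved unpenalized by maximum likelihood; if
the design is rank-deficient (e.g. identical local models produce
identical columns) the redundant directions get coefficient 0, and if the
solver fails to converge (perfect separation) a ridge-stabilized fit
(penalty 1e-6) is used and flagged. Which center hosts the meta-fit is
immaterial in simulation.

## Evaluation

Each center splits its own rows into stratified k folds (default 20);
iteration i holds out fold i of every center simultaneously, and the same
fold assignment serves every (regime, learner, imbalance) cell, so the 30
cells of the full matrix are compared on identical test folds. AUC is the
Mann–Whitney rank statistic; a test fold that ends up single-class (rare,
but possible with 10% prevalence at k = 20) records a missing AUC and is
excluded from that cell's mean and sample-sd with a warning, rather than
imputed. Mono-center and stacking cells re-run the grid search inside
every fold (leakage-safe); a configuration switch (`reuse_search`) fits
fixed hyperparameters instead. Cyclical cells always take hyperparameters
from configuration — searching inside a multi-round exchange protocol is
deliberately out of scope.

## Validation experiments and problem sizes

* **Pooled-equivalence**: two centers holding identical copies of one
  cohort (n = 400 training rows, 6 features, 20% prevalence) grow a
  50-tree forest cyclically; an ordinary 50-tree forest trains on the same
  rows. Mean AUC on an independent test cohort (n = 800) over 20
  replicates should differ by < 0.03 — the cyclical protocol over
  identical data is just a pooled forest grown in an unusual order.
* **Directional benchmark**: 20 simulated worlds from the shared logistic
  risk model (10 coefficients, n = 1160/631, 10% prevalence, covariate
  shift on three variables at the smaller center), evaluated with k = 5
  folds, forest + narrow network, class weighting, fixed hyperparameters.
  The claim checked is directional and averaged: mean held-out AUC at the
  smaller center under cyclical and under stacking is at least the
  mono-center mean. These sizes keep the full benchmark within minutes on
  one core while leaving the per-seed AUC differences well above fold
  noise after averaging.

## Known limitations

Feature independence within outcome strata understates real multivariate
structure, which tends to flatter simple learners; the in-sample
meta-features of stacking inherit the optimism noted above; the CWT
validation split reduces effective training data by its fraction; and
none of the published AUC values can be reproduced here, since they are
properties of the private cohorts — the package reproduces the protocols
and the direction of the comparison, not the numbers.
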