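# Methods

## The modelling problem

`hiermort` estimates mortality rates for multi-country insured
portfolios from *aggregated experience tables*: one record per unique
combination of rating-factor values within a country, carrying the
summed death count `D` and exposure-in-life-years `E`. Deaths are
modelled as

    D_ij ~ Poisson(mu_ij * E_ij),

where `mu_ij` is the mortality rate (deaths per life-year) of record
`i` in country `j`. This Poisson-with-offset formulation is the
standard device for survival analysis on grouped data: with piecewise
constant hazards, the Cox proportional-hazards likelihood coincides
with that of a Poisson regression with offset `log E`.

Rating factors split into *global* features — recorded and comparable
in every country (age, gender, calendar year, smoker status, product
attributes) — and *local* features that only some countries collect
and whose values and effects are not comparable across countries.
Local features carry missingness, either structural (a country never
collects the feature) or partial.

## The rate learner

Gradient-boosting libraries expose no offset term, so the model is
fitted as a weighted rate regression, which has the same likelihood:
target `D/E`, observation weights `E`, Poisson objective (LightGBM
backend). Consequences worth knowing:

* an intercept-only fit is exactly the portfolio rate
  `sum(D)/sum(E)`; we initialize the base score there explicitly
  (`boost_from_average` off), which makes the zero-tree model exact
  and the two-stage decomposition identities hold to machine
  precision;
* with a single categorical feature and enough boosting rounds, the
  per-category fitted rates converge to the per-category MLE
  `sum(D_c)/sum(E_c)` — the same estimates an IRLS-fitted Poisson GLM
  with offset `log E` produces; this equivalence is covered by a test
  against statsmodels;
* a per-record *initial score* (a starting log-rate) can be supplied;
  the ensemble boosts from it and therefore models only the residual
  factor.

### Leaf-support thresholds

Over-fitting control is expressed in actuarial units. For the Poisson
objective with exposure weights, the per-record hessian is
approximately the record's expected death count (LightGBM inflates it
by a constant `e^0.7` through its internal `max_delta_step`), so
LightGBM's minimum-hessian-per-leaf constraint bounds the *expected
deaths supporting a leaf*. `LearnerSpec` exposes:

* `min_deaths_per_leaf` (default **50**). A leaf supported by `m`
  expected deaths carries log-rate noise of roughly `1/sqrt(m)`; at 50
  this is ~0.14, small enough that the exponential aggregation bias
  `e^{sigma^2/2}` stays below one percent. Markedly smaller values
  (e.g. 5) let the boosting chase leaf-level Poisson noise, which both
  inflates fitted residual factors and makes data-scarce countries
  *over*-adjust — the opposite of the shrinkage behaviour the
  hierarchy is meant to deliver. Markedly larger values (e.g. 100+ in
  hessian units) can disable the residual stage entirely for a small
  country whose whole portfolio carries only a couple of hundred
  deaths.
* `min_exposure_per_leaf` (default 100 life-years), mapped through the
  portfolio rate onto the same hessian constraint; at typical insured
  rates (~1e-3) it is dominated by the death threshold and acts only
  as a guard for very low-rate segments.
* `min_gain` (default **1.0**): minimum loss reduction for a split, a
  chi-square-like evidence threshold. It applies to models fitted from
  scratch (global stage, local-only and pooled one-step benchmarks).

### The residual-stage spec

Local (residual) stages default to `residual_spec(spec)`:
`min_gain = 0` and half the tree budget. The reason is a degeneracy
specific to boosting *from an initial score*: a uniform country-level
correction (the most important residual component — the country's
overall level relative to the global model) produces **exactly zero
split gain**, because every candidate split leaves identical
gradient/hessian ratios on both sides. Such a correction enters leaf
values only through splits justified by *other* structure, so any
positive gain threshold leaves it systematically under-absorbed; we
observed fitted factors stalling at 1.7 where the truth was 2.0. With
the threshold removed, the correction is absorbed at the learning
rate's geometric pace; the halved tree budget limits the leaf-noise
accumulation the gain threshold would otherwise have pruned.

## The two-step model

1. **Global stage** — one learner on the pooled data of all
   countries, global features only.
2. **Local stage** — per country, a learner on global + available
   local features, with initial score `log q(x_global)` and base score
   pinned at 0, so it models a multiplicative correction `h_j`.

Because boosting adds tree scores in log space, the prediction
factorizes exactly:

    E[D | x, j] = q(x_global) * h_j(x_all) * E,

and a zero-tree local stage gives `h_j = 1` identically. Local
features entirely missing in a country's training data are dropped
from that country's stage. Onboarding a new country fits one new local
stage and leaves every existing prediction bit-identical.

The hierarchy performs no formal Bayesian shrinkage; partial pooling
is *implicit*: a local split must be supported by the country's own
expected deaths, so data-scarce countries stay close to the global
pattern while data-rich countries support stronger adjustments. An
optional per-country scalar balance factor (forcing the training
actual/expected ratio to 1) is provided but off by default.

Encoders are refitted at each stage on that stage's training data
(the alternative — reusing global-stage encoders — is supported
through the encoder objects but not the default, since local-stage
category rates are the relevant conditioning for local splits).

## Feature preparation

Missing cells are sentinel-imputed explicitly (`"Missing"` for
categorical, `-1` for metric), an operation kept separate from file
I/O so raw and model-ready tables remain distinguishable. The sentinel
is an ordinary category afterwards, letting trees use missingness as a
signal.

Categorical features are target-encoded: each level is replaced by its
exposure-weighted training mean of the observed rate `D/E` — i.e. the
level's raw mortality rate `sum(D)/sum(E)`. Training tables are
transformed *out of fold* (k = 5 by default, matching the tuning CV):
a record's encoding is computed from the other folds only, so it has
exactly zero dependence on the record's own target (verified by
finite perturbation). New data uses full-training means; unseen levels
fall back to the overall training mean. No shrinkage prior is applied
by default (`smoothing = 0`), though additive smoothing is available.

## Benchmark competitors

* **local** — an independent learner per country (global + available
  local features), seeing only that country's data;
* **one_step_single** — all countries pooled, all features, sentinel
  fill; features fully missing within a country are retained with
  sentinel values;
* **one_step_mice** — pooled data completed by bootstrapped
  decision-tree multiple imputation: 4 bootstrap resamples, 2
  iterations of per-variable tree imputation (classification trees for
  categorical variables, regression trees for metric ones, visiting
  variables in schema order from a sentinel initial fill), each
  missing cell drawing uniformly from the observed values in its leaf
  so the imputations carry sampling variation. One pooled model is
  trained per completed dataset — four models — and per-record
  predictions are averaged. Test tables are completed by replaying the
  trees fitted on the bootstrap training samples, never refitted on
  test. Variables missing everywhere cannot be tree-imputed; they are
  sentinel-filled and flagged. No Rubin's-rules pooling is involved:
  predictions, not parameter estimates, are averaged.

The pooled one-step models do not receive the country id as a
feature: the pooled feature set is the union of global and local
rating factors, and country identity reaches a pooled model only
indirectly (e.g. through missingness fingerprints). This is the
data-fusion setting the one-step strategies represent.

Evaluation per country and split: `rmse` (root-mean-square error of
predicted vs observed per-record death counts) and the Poisson
log-likelihood `sum(D log D_hat - D_hat)` (the `log(D!)` term,
constant in the model, is dropped). Log-likelihood is the primary
metric; RMSE on sparse counts mostly reflects the isolated-death
records. Best-strategy markers are computed from unrounded values.

Hyperparameter search (optional, off by default) is a seeded random
search over a declared space under grouped 5-fold cross-validation
whose folds never split a (country, year) cell; the global spec is
tuned first, then local specs against the frozen out-of-fold global
predictions, so no information flows between stages. Ties keep the
earliest candidate.

## The synthetic study

`default_study_config(scale)` emulates an eight-country primary-
insurance study: per-country unique-group counts, exposure totals,
death totals and observation-year ranges follow the shapes of a real
multi-country benchmark (countries from ~208k to ~4.8M unique groups,
~0.1M to ~1.8M life-years, ~300 to ~2100 deaths, two of the eight
data-scarce). The generator draws:

* nine global features (age, gender, calendar year, smoker status,
  product, sum-assured band, policy duration, distribution channel,
  individual/group indicator) with log-linear effects around a
  Gompertz baseline `a*exp(b*age)`, defaults `a = 2e-5`,
  `b = 0.09` — a plausible insured-lives age slope;
* a pool of six local features with country-specific availability,
  blockwise MCAR missingness fractions (including one structural
  absence), per-country *sign-varying* effect multipliers — the same
  occupation class can raise mortality in one country and lower it in
  another, reflecting the non-comparability of local codes across
  countries — and one pairwise interaction in two countries. Base
  magnitudes reflect realistic within-country differentials
  (hazardous-vs-professional occupation about 2x, extreme regional
  gaps about 1.6x);
* a per-country intercept calibrated analytically (independent-feature
  expectation of `exp(effects)`) so each country's expected overall
  rate reproduces the emulated study's death/exposure ratio.

`scale` multiplies the group counts only; per-group mean exposure is
set to `E_j / (N_j * scale)` so country-level exposure and death
totals stay at the study's magnitudes at every scale. The full-sized
table would be ~17M rows; at the default desk scale of 0.01 the table
has ~167k rows and the same ~9.4k expected deaths, which keeps the
strategy comparison statistically meaningful while fitting in minutes
on one CPU. Group exposures are log-normal (heavy-tailed group sizes);
masking is applied after the true rates are computed, so an unrecorded
value still drives mortality.

What the generator does **not** emulate: real feature dependence
structures (features are drawn independently within a country),
informative missingness (masking is MCAR given availability),
calendar-time shocks, and reporting artefacts. Passing tests therefore
demonstrate the *mechanics* of the method — identities, leakage
safety, shrinkage, and the qualitative strategy ordering under
heterogeneous data availability — not performance on any particular
real portfolio.

## Numerical and procedural choices

* Determinism: single-threaded LightGBM with `deterministic` mode and
  fixed seeds everywhere; a master seed derives stage seeds by hashing
  `"{master}:{stage}"`, so adding a stage never shifts another stage's
  randomness.
* Predicted rates are floored at 1e-12 before logs are taken in
  diagnostic metrics; `poisson_loglik` itself rejects non-positive
  predictions.
* An all-zero-death training set yields (with a warning) the floored
  constant-rate model; a zero-death country's local stage stays at
  `h_j = 1`.
* Train/test folds are stratified by country so every country appears
  in both splits; per-country train shares land within two percentage
  points of the target for countries with at least ~1000 records.
* Fold ties and tuning ties break toward the earliest candidate.
* The age-smoothness diagnostic is the mean absolute second difference
  of the predicted log-rate over an age grid at reference feature
  values (modal categories, median metrics); the generating Gompertz
  curve is exactly log-linear, so its score is 0 and fitted staircase
  curves are judged by an absolute band.

## Validation problem sizes

The test suite and the acceptance script run the study at scale 0.01
(~167k records, ~9.4k deaths), residual-recovery and shrinkage
scenarios with 50k and 4k groups per country, and replicate counts of
3–10 — sizes chosen so the full validation completes in minutes on a
single CPU while every qualitative claim is still measured, not
assumed.

## Known limitations

* The residual stage cannot represent a uniform correction through
  any single split's gain (see above); calibration of very small
  countries therefore converges geometrically rather than in one step,
  and extremely small countries (tens of deaths) may retain a few
  percent of aggregate miscalibration unless the explicit balance
  factor is enabled.
* Target encoding with `smoothing = 0` maps rare categories to noisy
  rates; the leaf-support thresholds, not the encoding, carry the
  regularization burden.
* MICE imputation trees condition on other features only (not on the
  outcome), which is deliberate — conditioning the imputation on
  death counts would leak the target into the features at prediction
  time — but it limits imputation quality when a local feature's best
  predictor is mortality itself.
* The tuning procedure refits on the full training set after model
  selection; out-of-fold scores are used for selection only.
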