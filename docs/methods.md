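# Methods

This note documents the models, algorithms and design choices behind
`pooltrend`, in the order the pipeline runs them.

## Data model and the synthetic generator

One observation is one pooled serum measurement: an OCP name, a design cell
(age group ∈ {5-15, 16-30, 31-45, 46-60, >60}, gender ∈ {male, female},
collection period ∈ {2002/03, 2006/07, 2008/09, 2010/11, 2012/13}), a
concentration in ng/g lipid and the number of individuals pooled. All
modelling is on the natural-log scale; the log base is a convention of this
package (the analysis is invariant to it up to rescaling of all location and
scale parameters).

`default_design()` reproduces the published 50-cell layout exactly: 154
pools, per-period totals 26/48/20/40/20, with the 5-15 group oversampled in
2006/07 (15 male + 17 female pools). Pools hold 100 individuals except
2006/07, where the protocol pooled up to 30; the fixed value 30 is used.
The 0-4 age group is excluded (it was not sampled in 2002/03, and the full
original layout including it is not reconstructible), which is why the
default design has 154 pools rather than the study total of 183.

The generator simulates each pool's log concentration as Normal(mean, σ),
where the mean is β_at (model 1), α_ag (model 2) or α_ag + β_at (model 3),
and β_at is either built forward from β_a0 by the random walk
β_at ~ N(β_a,t−1, ω²) or supplied verbatim (`beta_at`) to plant exact
interaction patterns. Pool size is recorded but does not scale the noise by
default — the models describe pool-level observations directly; an optional
flag applies σ/√(pool size) for design studies. All randomness flows through
explicit integer seeds; there is no global random state.

Two parameter sets are provided and used throughout the tests:

* `example_params(spec)` — generic study-realistic values: log levels
  rising with age from 3.0 to 4.6 (older cohorts lived through the
  agricultural use of OCPs), women 0.3 log units above men, σ = 0.5
  (within the 0.27–0.84 range of posterior observation SDs typical of such
  pooled data), ω = 0.2, φ = 0.3.
* `study_like_params()` — a fully planted model-3 truth emulating the
  observed regime: deterministic, non-parallel declines (slopes −0.05 to
  −0.17 log units per period, i.e. roughly −20% to −50% over the decade),
  a gender gap widening with age (0.1 to 0.4 log units), σ = 0.4. Because
  its temporal surface is explicit, replicate simulations differ only in
  observation noise, which makes it the right substrate for experiments
  about detecting structure (a drawn random walk is occasionally near-flat,
  in which case a time-free model legitimately fits as well).

What the generator does **not** emulate: individual-level variation within a
pool, covariates the pooled design cannot carry (BMI, breastfeeding,
occupation), laboratory error structure, and between-OCP correlation.
Passing tests therefore demonstrate correctness of the machinery and
calibration under the assumed model, not robustness to real-data
misspecification.

## Stage one: boosted regression trees

The screener is stagewise least-squares boosting: tree *m* is fitted to the
residuals of the ensemble of trees 1..m−1 and added with a shrinkage
(learning-rate) factor. All three predictors are categorical with at most
five levels, so trees split on exact level subsets — all 2^(k−1) − 1
bipartitions of a predictor's levels are enumerated and the split
maximizing the squared-error improvement is taken. Defaults: shrinkage
0.01, depth 3 (allows three-way interactions), up to 5,000 trees. Half the
data trains the ensemble and half drives early stopping (stratified by
design cell so that small cells appear in both halves; with odd cells the
global halves differ by at most one); boosting stops when the held-out
deviance has not improved for 50 rounds or no improving split exists, and
the ensemble is truncated at the best held-out iteration. The training
deviance trace is non-increasing by construction.

Since the feature space has only 50 cells, ensemble predictions are cached
on the full design grid; partial dependence and interaction grids are exact
weighted averages of that table under the empirical training distribution.

* **Relative importance**: the squared-error improvements of all splits on
  a predictor are summed over the ensemble and rescaled so the three
  importances total 100. Undefined (an explicit error) if no split exists.
* **Interaction strength**: for a predictor pair, the two-way
  partial-dependence grid is fitted with an additive main-effects linear
  model; the mean squared residual is returned, unnormalized. Stump
  ensembles (depth 1) are additive and score exactly zero.
* **Partial dependence**: per-level average prediction with the other two
  predictors marginalized over their joint empirical training distribution,
  centred so the training-frequency-weighted mean effect is zero.

## Stage two: hierarchical models

The three model specs and their priors are listed in the README. Points of
note:

* **Gender in model 1.** The model-1 mean is β_at only — gender enters none
  of its terms, so its posterior is exactly invariant to swapping the gender
  labels (the sampler aggregates over gender before any arithmetic, making
  the invariance bit-exact). A per-gender offset α_g ~ N(0, 10⁴) can be
  added to the mean via `include_gender_offset=True` for sensitivity
  analyses.
* **Random-walk index.** β_a0 is a latent pre-series state with prior
  N(0, ω²); the first observed period (2002/03) is t = 1 with
  β_a1 ~ N(β_a0, ω²).
* **Scale priors** are Uniform(0, 100) on the standard-deviation scale;
  location priors are Normal with variance 10⁴.

### Sampler

Estimation is by Gibbs sampling with exact conditionals. All location
parameters (β blocks vectorized over ages, α over cells, δ, α_g) have
conjugate normal full conditionals. Under the uniform-SD prior each scale's
conditional on the variance is InverseGamma((m−1)/2, SS/2) truncated at
100², drawn by rejection from the untruncated distribution (the bound
essentially never binds once data are present) with an inverse-CDF fallback;
degenerate cases (m ≤ 1) fall back to grid inversion of the SD density.

In model 3 the likelihood is flat along (α_a· + c, β_a· − c) for each age —
only the sum α_ag + β_at is identified. To keep the chains mixing across
that ridge, each iteration ends with an exact recentring move: the shift c
has a Gaussian conditional determined by the priors alone and is drawn and
applied per age (a Gibbs update along the flat direction, which leaves the
posterior invariant). The same move is applied between α_g and the β level
when the model-1 gender offset is enabled. Reported inference on model 3
should focus on identified quantities — cell means, trajectories, changes —
not on individual α or β levels.

Defaults follow the study protocol: 2 chains × 10,000 kept iterations after
10,000 burn-in. Initialization: location parameters at the empirical grand
mean of the log concentrations (offset by 0, +1, −1, … across chains),
scales at 1 (alternating 2) for overdispersed starts. Convergence is
summarized by the Gelman–Rubin PSRF (Brooks–Gelman corrected point estimate
with an F-quantile upper bound); fits are conventionally accepted when all
PSRF < 1.1. Identical seeds give bit-identical draws.

## Assessment

* **Predictive intervals**: for each observation, a posterior-predictive
  sample is formed by adding fresh Normal(0, σ-draw) noise to the per-draw
  fitted mean (one predictive draw per posterior draw; ≥ 2,000 with the
  reduced test settings, 20,000 at defaults). The observed coverage of the
  central (1−α) empirical interval is reported for α = 0.2, 0.1, 0.05.
  Coverage is monotone in the nominal level by construction of nested
  central intervals.
* **DIC**: conditional on the lowest-level parameters (the JAGS-style
  convention), with θ\* the posterior mean of all parameters including σ.
  D̄ is the posterior mean deviance, p_D = D̄ − D(θ\*), DIC = D(θ\*) + 2p_D;
  the identities hold to machine precision by construction and are asserted
  in tests. p_D can in principle be negative for badly mixed fits; this is
  reported as-is.
* **RMSE**: root mean squared residual of the posterior-mean fitted values,
  on the log scale.
* **Ranking**: models are ordered by DIC; ties are flagged, never broken
  silently. RMSE and the distance of each coverage from its nominal level
  are reported alongside without aggregation.

## Trend and change inference

Percent changes are computed draw-wise on the concentration scale,
100·(exp(m₂) − exp(m₁))/exp(m₁), then summarized by the posterior mean and
central 95% interval — so the interval is a genuine credible interval of
the percent change, and the draw-wise overall change composes exactly from
the consecutive-period changes. Model 2 has no temporal term; requesting a
change from it raises a dedicated error rather than returning anything.

The cohort extrapolation compares age band *a* at the first period with
band *a + 1* at the last. The bands are 10–15 years wide while the study
spans 10 years, so the mapping is approximate by construction; the
adjacent-band convention is used and labelled explicitly in the output.

The sensitivity assessment randomly thins the oversampled 5-15 / 2006/07
cell to 4 pools per gender, refits all three models on the full and reduced
data, and reports paired posterior means (β_at for model 1, α_ag for
model 2, their sum for model 3) with posterior SDs, so "no material change"
can be judged on the posterior's own scale.

## Problem sizes and numerical choices

The test suite and the acceptance script run reduced MCMC (2 chains ×
2,000 kept iterations after 2,000 burn-in) and moderate ensembles (≤ 1,500
trees); these sizes were chosen as the smallest at which the Monte-Carlo
experiments (conjugate-oracle agreement, 95%-interval coverage over 20
replicates, DIC model selection over 10 replicates, predictive calibration
at 300 pools) are stable. Splits require a strictly positive improvement
(> 1e-12); coverage and interval summaries use empirical quantiles; the
truncated inverse-gamma rejection loop is capped at 64 draws before the
exact inverse-CDF fallback.

## Known limitations

* One OCP per run; multivariate modelling of correlated OCPs is out of
  scope (a batch over OCPs is a loop).
* No informative or elicited priors.
* Conditional (not marginalized) DIC; WAIC/LOO are not computed.
* The BRT stage handles categorical predictors only.
* Model-3 level parameters are reported but not individually identified
  (see above).
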