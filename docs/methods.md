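# Methods

`pdcshift` estimates the causal effect of a small, realistic improvement in
medication adherence on a binary outcome, using a shift-intervention
(modified treatment policy) estimand and targeted minimum loss-based
estimation (TMLE). This note records the model, the estimator, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Estimand

Each subject contributes O = (W, A, Y): confounders W, adherence A ∈ [0, 1]
measured as proportion of days covered (PDC), and a binary outcome Y
(death after infection). The data are modelled by a nonparametric
structural equation model W = f_W(U_W), A = f_A(W, U_A), Y = f_Y(W, A, U_Y)
with independent subjects.

The hypothetical intervention adds δ to each subject's observed adherence
unless that would exceed the conditional support bound u(w):

    d(a, w; δ) = a + δ  if a ≤ u(w) − δ,   else  a.

The target parameter is Ψ = E[Y] − E[Y_d], the absolute reduction in
outcome risk under the shifted adherence distribution; positive values mean
the intervention reduces risk. Identification requires no unmeasured
confounding and positivity: the shifted adherence must stay inside the
support of the observed adherence given covariates. Positivity is
operationalized by the density ratio r(a, w) = g_d(a | w) / g(a | w), where
g is the conditional density of A given W and g_d its pushforward under d:

    g_d(a | w) = g(a − δ | w)·1{l(w) + δ ≤ a ≤ u(w)} + g(a | w)·1{a > u(w) − δ}.

A shift is flagged infeasible when the maximum of r over the sample reaches
the configured bound (default 10); the 0.99 quantile and the exceedance
fraction are reported alongside. Flagging uses the maximum — the
conservative reading — because a single extreme weight is enough to
destabilize the estimator. Default support bounds are the natural PDC
limits l(w) = 0, u(w) = 1 (a data-adaptive empirical maximum is available);
default shifts are δ ∈ {0.05, 0.10}.

## PDC from refill records

`days_covered` simulates a daily pill stock: each dispensing adds
boxes × tablets-per-box tablets; every day on which the stock covers the
prescribed daily dose is a covered day and consumes that dose. Leftover
supply carries over without limit inside the observation window. The
implementation is event-driven interval arithmetic over refill dates and is
tested for exact equality against a brute-force day-by-day simulation.
Conventions: dates are whole days and the dispense day itself is coverable;
the window runs from the first in-scope dispense date to the day before the
qualifying positive test (both configurable); supply dispensed before the
window is consumed from its dispense date and only the remainder carries
in, so pre-window days are never counted. PDC = covered days / window
length, capped at 1. The daily regimen defaults to two 850 mg tablets per
day (a common regimen; the source registry does not record it) and can be
set per record. The conventional PDC ≥ 0.8 adherence label is provided for
description only; the estimand never dichotomizes adherence. These
conventions make PDC an upper bound on true intake (pills dispensed are not
necessarily taken), which biases effect estimates toward the null.

## Cohort construction

Inclusion requires at least one positive SARS-CoV-2 test and dispensings in
two adjacent calendar months strictly before the most recent positive test;
single-prescription patients are excluded. An attrition log records counts
after each rule. Epidemic waves are assigned from the most recent positive
test by the printed calendar windows (wave 1: 2020-03-29–2020-10-03;
wave 2: –2021-05-29; wave 3: –2021-12-18); tests from 1–28 March 2020
predate the first window and fold into wave 1 by default so the partition
is exhaustive. Facility-level covariates with missing entries are imputed
with the observed median and flagged with a per-variable indicator column;
patients missing individual-level pre-existing-condition data are dropped,
not imputed. Mortality is ascertained as any death flag after the
qualifying test (the follow-up horizon is configurable).

## Nuisance estimation

Two nuisances are estimated. The outcome regression Q̄(a, w) = E[Y | A = a,
W = w] is fit by a super learner: V-fold cross-validation (default V = 10)
of each candidate learner under binomial log-loss, followed by a convex
weight vector on the simplex minimizing the cross-validated loss of the
combined prediction (SLSQP; discrete best-single-learner fallback), and a
refit of every member on the full data. The default library is
intercept-only, main-terms logistic regression, gradient-boosted trees
(depth 3), and a random forest; a learner whose fit raises is dropped with
a warning. Predictions are clipped to [1e−6, 1 − 1e−6].

The exposure density g(a | w) has two estimators:

* **Binned pooled hazard** (default): [0, 1] is split at empirical
  quantiles of A into B = 20 equal-mass bins (duplicate edges merged;
  equal-mass avoids empty bins at the heavy 0.8–0.9 mode), a binary hazard
  classifier is fit on the pooled subject-by-bin expansion with one-hot bin
  indicators plus W as features, and bin probabilities are discrete-hazard
  products renormalized per subject; the density is bin probability over
  bin width. One-hot bin features make the hazard saturated in the bin
  dimension, so a uniform exposure yields a flat density without any
  smoothness assumption across bins.
* **Beta regression** (`method="beta"`): A | W ~ Beta(μ(w)φ, (1 − μ(w))φ)
  with logit μ linear in W and common concentration φ, fit by maximum
  likelihood with analytic gradients (covariates standardized internally —
  an affine reparameterization). This is the correctly specified
  parametric choice for the synthetic model and is what the recovery and
  coverage simulations use.

All stochastic learners receive seeds derived deterministically from a
top-level seed and a stage name. Cross-fitting of the nuisances (K-fold,
out-of-fold evaluation before a single global fluctuation) is available but
off by default.

## Targeting and inference

The initial substitution estimator is Ȳ − (1/n) Σ Q̄(d(aᵢ, wᵢ; δ), wᵢ),
with the empirical distribution of W as the plug-in for its marginal. The
fluctuation is a weighted intercept-only logistic submodel
logit Q̄_ε = logit Q̄ + ε with weights r(aᵢ, wᵢ), solved exactly by
one-dimensional root finding of the weighted score (Brent's method,
xtol 1e−14); the intercept-with-weights form is numerically stabler than
putting the ratio inside the submodel when weights are large, and solves
the same score equation. Targeting iterates (at most 10 times) until the
residual score mean satisfies |(1/n) Σ r(yᵢ − Q̄*)| < se/(√n·log n); the
intercept submodel solves it in one step in practice.

The estimate is ψ = Ȳ − θ*, θ* = (1/n) Σ Q̄*(d(aᵢ, wᵢ; δ), wᵢ) — a
substitution estimator, so θ* ∈ [0, 1] by construction. Inference uses the
efficient influence function

    Dᵢ = (yᵢ − Ȳ) − [ r(aᵢ, wᵢ)(yᵢ − Q̄*(aᵢ, wᵢ)) + Q̄*(d(aᵢ, wᵢ), wᵢ) − θ* ],

with se = sd(D)/√n and a Wald 95% interval ψ ± 1.96·se. No finite-sample
variance inflation and no multiple-testing adjustment are applied (per-
stratum Wald intervals are reported as-is). An infeasible positivity
diagnostic does not suppress the estimate; it attaches a warning flag.

`run_analysis` orchestrates, for each δ: the overall estimate, per-wave
estimates (nuisances refit within each stratum; covariates constant within
a stratum are dropped there), vaccinated/unvaccinated subgroup estimates,
and a negative-control analysis that reruns the identical estimator with
the outcome column swapped to the test-result indicator — an outcome that
shares confounders with adherence but is not caused by it, so a non-null
estimate signals residual bias. `substitution_curve` reports per-subject
predicted risk changes Δᵢ = Q̄(d(aᵢ, wᵢ), wᵢ) − Q̄(aᵢ, wᵢ) (exactly zero
for unshifted subjects) with a penalized B-spline smooth (cubic basis,
second-difference penalty, λ = 1) against baseline adherence per stratum,
plus before/after adherence histograms.

## Synthetic validation model

Because the source registry is confidential, every stage is validated
against a fully specified structural causal model with a computable
counterfactual truth.

* **Confounders (14)**: age ~ N(58, 12²) clipped to [18, 95]; sex ~
  Bern(0.48); four pre-existing-condition indicators (hypertension 0.45,
  obesity 0.35, chronic kidney disease 0.08, cardiovascular disease 0.12);
  months on metformin ~ logN(log 14, 0.55²) clipped to [2, 48] (median 14);
  vaccine doses (zero in wave 1, Bernoulli 0.08/0.35 in waves 2/3, one or
  two doses); six facility variables (log-normal population; Beta
  insurance-affiliation, disabled and illiteracy proportions; normal
  education years and occupants per room).
* **Waves**: multinomial with weights (0.355, 0.465, 0.180) matching the
  relative wave sizes of the emulated study; test dates uniform within each
  wave window (capped at October 2021). Epidemic dynamics are deliberately
  not modelled.
* **Adherence**: A | W ~ Beta(μφ, (1 − μ)φ), logit μ linear in
  standardized covariates, φ = 9.234. The intercept (1.4381) and φ were
  calibrated once by Monte Carlo (n = 2×10⁶) so the marginal moments hit
  the emulation targets mean 0.81, sd 0.13.
* **Outcome**: Y | A, W ~ Bernoulli(expit(c_wave − 1.2·A + β'z(W))) with
  wave intercepts (0.1428, 0.3731, 0.4640) calibrated to per-wave mortality
  31.8%/35.9%/35.8%. Age, comorbidities, education and housing density
  enter both the adherence and outcome equations, producing genuine
  confounding; all standardizations used in the structural equations are
  affine in the raw analysis columns (facility population, the one
  log-transformed variable, carries zero structural weight), so a
  main-terms logistic regression on the analysis table is an exactly
  correct outcome model.
* **Negative control**: Bernoulli in W only — its true shift effect is
  exactly zero by construction.
* **Missingness**: facility variables blanked completely at random at
  per-variable rates between 3% and 12%; individual variables untouched.
* **Raw tables**: refill records are synthesized from a monthly skeleton of
  30-tablet boxes at two tablets/day — two boxes per month while bulk
  supply lasts (spread over at least two calendar months) plus one trailing
  box timed so that exactly the remainder of the target covered days falls
  before the window end. Recomputing PDC from these records recovers the
  generator's A to within 0.5/window-length ≤ 0.01 for every patient. A
  target adherence below two boxes' coverage is structurally incompatible
  with the two-consecutive-month inclusion rule; such (very rare) draws
  raise an error by default or, in pipeline mode, are clamped to the
  two-box minimum with a warning.

`true_shift_effect` computes ψ(δ) by drawing (W, A) from the model,
applying the shift rule, and averaging the difference of structural outcome
probabilities at the observed and shifted adherence (default 10⁶ draws;
Monte-Carlo SE reported; ψ(0) = 0 exactly).

### A note on positivity in the synthetic model

With marginal moments fixed at mean 0.81 and sd 0.13, any Beta adherence
model has density vanishing at 1, so the *true* density ratio is unbounded
near the top of the scale and the sample maximum routinely exceeds 10 at
δ = 0.1. Real PDC data concentrate a point mass at perfect adherence
instead, and binned density estimators (like the pooled hazard used in the
emulated analysis) bound the estimated ratio by construction. The
feasibility diagnostic therefore often flags δ = 0.1 on synthetic cohorts
even though estimation remains stable; the flag is honest output of the
conservative max-ratio rule, not an error.

## Validation experiments and their scale

All experiments use fixed seeds and run on one CPU; problem sizes were
chosen so the full suite completes in a few minutes while leaving the
Monte-Carlo error well below the quantities being tested.

* **Recovery**: 200 replicates at n = 2000, δ = 0.1, correctly specified
  parametric nuisances (main-terms logistic Q̄, beta-regression g); the
  mean estimate must sit within a quarter of the replicate sd of the
  10⁶-draw oracle truth.
* **Coverage**: 500 replicates at n = 1000 with the same reduced parametric
  library; Wald 95% coverage must land in [0.92, 0.97].
* **Double robustness**: with exactly one nuisance replaced by an
  intercept-only fit (the other correctly specified), absolute bias must
  fall monotonically over n ∈ {1000, 4000, 16000} (300/150/75 replicates)
  and be statistically indistinguishable from zero at the largest n. This
  experiment uses δ = 0.25: at δ = 0.1 the doubly-robust correction is so
  effective that the residual bias is below Monte-Carlo resolution already
  at n = 1000, leaving nothing measurable to decay; the larger shift
  stresses positivity enough to make the misspecification bias visible.
* **Negative control**: 500 replicates at n = 1000 targeting the
  control outcome; mean within two Monte-Carlo SEs of zero and nominal
  coverage of zero.
* **Score equation**: every targeted fit in the above must satisfy the
  residual-score criterion.

What passing these experiments does *not* show: the synthetic model is
logit-linear with independent subjects and completely-at-random
missingness; real claims data have point masses in PDC, informative
missingness, clustering within facilities, and unmeasured severity markers
(e.g. HbA1c). The experiments validate the estimator's statistical
machinery, not the causal assumptions on any particular real dataset.

## Known limitations

* The conditional support bound u(w) defaults to the constant 1; the
  data-adaptive option is a crude within-sample maximum.
* The pooled-hazard density uses a fixed bin count; its ratio tails are
  bounded but its density values plateau within bins.
* Heavy density-ratio tails (see the positivity note) inflate the EIF
  variance near perfect adherence; coverage at small n sits near the lower
  edge of the nominal band.
* The weighted-intercept fluctuation assumes a binary (or [0, 1]-valued)
  outcome; continuous outcomes are out of scope.
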