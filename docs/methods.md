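# Methods

## Estimand and model

The target is the subject-specific (conditional) risk ratio in a
log-linear binomial mixed model for clustered binary outcomes
`Y_ij ∈ {0,1}` (cluster `i = 1..N`, unit `j = 1..n_i`):

    log Pr(Y_ij = 1 | x_ij, eta_i) = x_ij' beta + eta_i,
    eta_i ~ N(0, tau^2),

so `exp(beta_k)` is the risk ratio per unit of covariate `k`, holding the
cluster effect fixed. This model is never fitted directly — its ML
estimates frequently do not exist because the log link lets fitted
probabilities exceed 1. Instead, the estimator is:

1. **Augment.** For every observed event row, append one copy with the
   outcome set to 0, identical cluster label and covariates, flagged
   `is_pseudo`. With `m` events among `n` units in a covariate stratum the
   augmented odds are `m / n`, the original risk: odds on the augmented
   data are risks on the original data.
2. **Fit.** Maximize the ordinary random-intercept *logistic* GLMM
   likelihood on the augmented data. The fixed-effect estimates are
   consistent for the log-linear model's `beta`, so `exp(beta_hat)` are
   risk ratios. On fully stratified data the identity is exact and
   algebraic, not just asymptotic (asserted to machine precision in the
   tests).
3. **Bootstrap.** The augmented rows are artificial, so neither the
   inverse information nor the usual estimating-equation argument gives a
   valid variance. Uncertainty comes from a cluster nonparametric
   bootstrap: draw `N` clusters with replacement, relabel (a cluster drawn
   twice becomes two distinct clusters), re-augment the resample, refit;
   percentile confidence limits and an add-one two-sided sign-count
   p-value come from the `B` coefficient samples.

Rows with a missing outcome are dropped before augmentation. Under a
missing-at-random mechanism the missingness factorizes out of the
observed-data (pseudo-)likelihood, so this direct-likelihood handling
leaves the estimator's mean unchanged — an ignorability property the test
suite verifies empirically against complete data. Rows with missing
covariates are rejected rather than imputed.

## The GLMM fitter

Only a scalar random intercept is supported (`z_ij = 1`); that is the
structure of every intended application, and it keeps the integral
one-dimensional. Estimation is plain ML (not REML) over `(beta, log tau)`.

**Adaptive Gauss–Hermite quadrature.** Each cluster's marginal likelihood
integral is approximated with nodes centred at the conditional mode of the
integrand (found by a damped, vectorized Newton iteration, warm-started
across likelihood evaluations) and scaled by the curvature there; default
25 nodes, `n_nodes=1` giving the Laplace approximation. On small clusters
the approximation agrees with dense brute-force quadrature to better than
six significant digits, and converges below 1e-6 absolute error well
before 25 nodes.

**Gradient.** The optimizer (L-BFGS-B) receives the marginal score via
Fisher's identity — the posterior expectation of the complete-data score,
evaluated with the same quadrature weights — which is exact up to
quadrature error and costs one extra matrix pass per evaluation.

**Boundary handling.** `log tau` is bounded below at `log(1e-4)`. Before
any quadrature the fitter evaluates the variance-component score-test
slope at the plain-logistic MLE: the derivative of the profile
log-likelihood with respect to `tau^2` at `tau → 0` is
`(1/2) Σ_i (g_i² + h_i)`, with `g_i`, `h_i` the first two derivatives of
cluster `i`'s conditional log-likelihood in `eta` at 0. When the slope is
non-positive the optimum lies on the boundary and the exact
iteratively-reweighted-least-squares logistic MLE is returned immediately
with `boundary_tau=True`; the same refit happens when the optimizer stops
at the bound (or at `tau < 1e-3` with no likelihood gain over the plain
fit). Besides exactness at the boundary, this shortcut is what makes the
bootstrap cheap: under small `tau` most resample fits never need the
optimizer at all. Fits never silently fail — non-convergence is flagged,
and any `|beta|` component exceeding 30 raises a separation error
(penalized estimation is out of scope).

**Convergence.** Gradient max-norm below 1e-6 or relative log-likelihood
change below 1e-10, at most 500 outer iterations. The fit is deterministic
given the data, node count and tolerances, and invariant to row and
cluster relabeling/permutation.

## Bootstrap details

- Default `B = 1000`; below 50 a warning is raised (percentile limits need
  large `B`).
- Percentile limits use the inclusive linear-interpolation ("type 7")
  quantile definition; at `B = 1000` different conventions move limits in
  the third decimal, so the choice is pinned and documented.
- p-value: `2 · min{(1 + #{b ≤ 0})/(B+1), (1 + #{b ≥ 0})/(B+1)}`, capped
  at 1 — chosen for exactness at the boundary and consistency with the
  percentile interval (no standard formula exists for this setting).
- Each replicate draws from an independent RNG stream spawned from
  `(seed, b)`, so results are bit-identical whether replicates run
  serially or across workers.
- Resample fits that fail (separation, non-convergence) are dropped and
  counted, never redrawn — redrawing would condition the resampling
  distribution on fit success; above 5% failures a warning is attached.
- The reported `tau` is from the single observed-data fit; bootstrap `tau`
  samples are exposed but not summarized into an interval.

## Sandwich comparator

`pseudorr.sandwich` implements the cluster-level sandwich
`A⁻¹ B A⁻ᵀ` (A: finite-difference Hessian of the total augmented
log-likelihood on `(beta, log tau)`; B: outer products of per-cluster
finite-difference scores, step `1e-5 · max(1, |theta|)`). It exists as a
comparator for the inference method a practitioner might reach for first.
Two empirical facts, both asserted in the tests: the *row-independence*
(model-based) variance on augmented data is severely biased — duplicated
pseudo-rows overstate the information by roughly half in the evaluation
cells — while the cluster-level sandwich tracks the true sampling SD of
the treatment coefficient closely in those same cells, consistent with
M-estimation theory for independent clusters. The bootstrap remains the
supported inference route: it requires no large-N variance expansion and
behaves well at the moderate cluster counts (N = 50) where analytic
variances are least trustworthy. Variances are reported on `(beta,
log tau)`; the delta method gives `Var(tau) = tau² · Var(log tau)`.

## Synthetic data generator

The generator emulates a 4-visit longitudinal trial. Per participant
(cluster): treatment, baseline symptom, centre and gender are
Bernoulli(0.5); age is an integer uniform on [11, 68], centred at the
design mean 39.5 before entering the linear predictor (centring only
shifts the intercept but keeps the log-link's valid region symmetric in
age). Covariates are constant across a participant's four visits; there
is no visit-level term. Outcomes follow the log-linear mixed model above
with coefficients `(beta1, 0.71, 0.28, -0.05, -0.01)` — the non-treatment
values being estimates from a real respiratory trial — and random
intercept SD `tau ∈ {0.02, 0.05, 0.10}` in the standard grid.

**Intercept calibration.** `beta0` is set by bisection so that the
Monte-Carlo mean event probability over 1e5 simulated participants
(common random numbers, so the objective is deterministic and monotone)
hits the target overall event frequency within 0.002. Probabilities that
the log link pushes to or above 1 are clipped at `1 - 1e-8`; the clip
fraction is recorded on every simulated dataset, warned about above 1%,
and calibration refuses targets that cannot be met without exceeding that.
In the 40%-event cells with the largest treatment effect the clip
fraction is a few tenths of a percent.

**MAR dropout.** From visit 2 onward a participant still in the study
drops with probability `expit(xi0 + log(1.5) · Y_prev)`; dropout is
monotone (all outcomes from the dropout visit onward are missing;
visit 1 is always observed). Because the hazard depends only on the
previously *observed* outcome the mechanism is MAR. `xi0` is calibrated by
bisection of the exact conditional dropout probability averaged over 1e5
simulated outcome paths so that 20% of participants ever drop out.
"Fraction of participants ever dropping" is the adopted reading of the
total dropout rate; `dropout_metric="visit"` switches to the fraction of
visit-slots missing. In an event-free population the calibrated value has
the closed form `logit(1 - 0.8^(1/3))`, which the tests check.

**What the generator does not emulate.** The reference evaluation for
this estimator resampled covariates from a real trial population; the
synthetic Bernoulli/uniform stand-ins reproduce the stated marginals but
not the real joint distribution. The pseudo-observation estimator's mean
is insensitive to this (it is consistent for the data-generating `beta1`
under either covariate law, and the harness confirms the published
risk-ratio means within Monte-Carlo error), but quantities that depend on
the covariate-induced risk heterogeneity are not: the *odds-ratio*-scale
mean of the ordinary logistic GLMM is noncollapsible, and its
large-sample value under the synthetic covariates is ≈0.93 in the
N=100 / 40%-event / beta1=0.47 cell versus ≈1.01 under the real-data
covariates. Passing harness checks therefore certify the estimator's
behaviour, not a reproduction of every comparator column digit.

## Evaluation harness

`run_scenario` generates replicate datasets, analyzes each with the
ordinary logistic GLMM (log odds-ratio scale, Wald interval from the
finite-difference observed information when intervals are requested) and
the pseudo-observation estimator (log risk-ratio scale, percentile
bootstrap), and aggregates Mean, SE (SD of estimates), SE-hat (mean
estimated SE), RMSE, coverage rate and expected width for the treatment
coefficient against the true `beta1` on the log-RR scale — for the
OR-scale estimator the gap from `beta1` is scale discordance, not
estimator failure, and is reported as such. Replicates derive per-rep RNG
streams from the scenario seed (results independent of the worker count);
failed replicates are dropped and counted.

The default evaluation scale in the tests and the acceptance script is
200 replicates per cell and 200 bootstrap resamples (the reference grid
used 1000/1000); Monte-Carlo tolerances in the tests are widened
accordingly (3–4 standard errors at the reduced scale).

## Known limitations

- Random intercepts only: no random slopes, crossed or non-nested
  effects, and no non-normal random-effect distributions.
- The estimand is the subject-specific risk ratio; marginal
  (population-averaged) standardization is out of scope.
- No penalized fallback under separation; the fitter raises instead.
- Percentile intervals (no BCa/studentized variants) and nonparametric
  cluster resampling only.
- The log-link clip at `1 - 1e-8` is a declared policy for the DGP's
  invalid-probability region, not a statement about real data.
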