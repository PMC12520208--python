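# Methods

`heatlmtp` estimates the causal effect of warmer daily temperatures on a
log-transformed early-vocabulary score using longitudinal modified
treatment policies (LMTP).  This note documents the model, the
estimator, the synthetic cohort used for validation, and the numerical
and design choices a maintainer should know about.

## Causal model and estimand

Each child contributes a 120-week exposure calendar: gestation weeks
1–30 followed by postnatal weeks 1–90, concatenated into 840 daily
temperatures and partitioned into 12 ten-week periods.  The exposure
for period *t* is the number of **heat spikes** `A_t`: maximal runs of
at least two consecutive days with the daily indicator (overall,
daytime, or nighttime temperature) strictly above a high percentile
threshold of the pooled daily distribution.  Cold spikes `C_t` —
the mirrored count below the 10th percentile — enter as a time-varying
confounder.  The outcome `Y = log(score + 1)` is a 0–100 word-production
score on the log scale.

The intervention is the additive shift `d(Temp, k) = Temp + k` applied
to every daily temperature, with `k ∈ {1, 2, 3}` °C; the counterfactual
exposure `A_t^d` is the spike count of the shifted series at the same
threshold.  The estimand is

    theta = E[Y^d] − E[Y],

the difference between the counterfactual population mean under `k`
degrees of warming and the natural-course mean.  Because the outcome is
log-transformed, theta reads approximately as a relative change in the
score; `exp(x) − 1` maps a log-mean back to the score scale.

Shifts are restricted to |k| ≤ 5 °C: modest shifts keep the
counterfactual exposure distribution inside the support of the factual
one, which is what makes the positivity assumption tenable.

## Estimation

1. **Density ratios.**  For each period,
   `r_t = g_t^d(A_t | H_t) / g_t(A_t | H_t)` — the longitudinal
   analogue of a stabilized weight — is estimated by the classification
   trick: stack the observed `(H_t, A_t)` rows (label 0) against
   `(H_t, A_t^d)` rows (label 1), fit a probability model, and convert
   the fitted probability at the observed row to an odds.  The history
   `H_t` is conditioned in full (baseline covariates, `C_1..C_t`,
   `A_1..A_{t−1}`; no Markov assumption).  Classes are stacked 1:1, so
   no prevalence correction is applied.  Probabilities are clipped to
   `[1e−6, 1 − 1e−6]` (clipping events are logged).  Ratios above the
   pooled empirical 99.9th percentile (lower order statistic) are capped
   there; the truncation scope and quantile are configurable.

2. **Sequential-regression TMLE.**  With the outcome rescaled to [0, 1]
   by the data-independent bounds `[0, log(101)]`, the backward
   recursion over t = 12..1 regresses the current pseudo-outcome on
   `(H_t, A_t)`, applies an intercept-only logistic fluctuation whose
   loss is weighted by the cumulative truncated ratios
   `w_t = prod_{s≤t} r_s`, and carries the targeted prediction at
   `(H_t, A_t^d)` back as the next pseudo-outcome.  Working on the
   logit scale keeps every targeted prediction — hence the final
   estimate — inside the outcome bounds for any weights.  The
   fluctuation solves the weighted score equation by bracketed root
   finding (`|eps| ≤ 20`, tolerance 1e−12); separation falls back to a
   zero fluctuation with a warning.

3. **Inference.**  The per-child efficient influence function
   `phi_i = Σ_t w_{t,i}(m̃_{t+1,i} − m̌_{t,i}) + m̃_{1,i} − psi` yields
   `se = sd(phi)/√N` and Wald 95% intervals.  The natural-course mean is
   estimated by the identity-shift TMLE (ratios ≡ 1), which reproduces
   the empirical mean up to the fluctuation tolerance; theta's standard
   error comes from the per-child EIF *difference*, which accounts for
   the covariance between the two estimates.  P-values are two-sided
   normal and unadjusted across scenarios (the report logs how many
   scenarios a grid ran).

4. **Stacked ensembles.**  Outcome regressions and ratio classifiers use
   a SuperLearner-style stack: V-fold cross-validated member
   predictions, convex meta-weights minimizing squared error (via
   non-negative least squares polished to the simplex optimum) or log
   loss (constrained minimization), members refit on the full data.
   The `full` library holds a main-effects linear model, a
   ridge-shrunken (Bayesian-style) linear model, an L1-regularized
   linear model with CV-tuned penalty, a penalized additive spline
   model, a random forest, gradient-boosted trees, and a constant-mean
   benchmark.  The `fast` library (linear, CV-lasso, small gradient
   boosting, mean) is the default for tests and simulations; member
   hyperparameters are library defaults.  Five folds by default
   (three in the test suite).

   For the ratio classifiers the stack additionally receives an
   engineered block — the current count, its square, and interactions
   with period-aligned covariates — plus a screened logistic member
   restricted to that block.  For count-valued exposures under a shift,
   the true log density ratio is (near-)quadratic in the count with a
   climatology-dependent slope, so this parametric candidate is close to
   correctly specified; without it, log-loss stacking at moderate N
   shrinks the fitted ratios toward 1, which both under-corrects the
   outcome model and deflates the EIF variance estimate below the
   efficiency bound.  The meta-weights still decide whether the
   candidate is used.

5. **Cross-fitting** of the outcome regressions is available behind
   `cross_fit=True` (sample-splitting for EIF-condition robustness); the
   default is off.

## Synthetic cohort

Real birth-cohort data being confidential, validation uses a generator
with known counterfactual truth.

*Weather.*  Daily overall temperature is
`T_i(d) = 11.83 + 8·sin(2π(d + start_i − 91)/365) + b_i + e_i(d)` with a
child-level climate offset `b_i ~ N(0, 0.3²)` and stationary AR(1)
anomalies (`rho = 0.7`, marginal SD 3.5 °C — typical day-to-day
variability for France).  `start_i` is the conception day of year: one
of four enrollment waves plus ±3 weeks of spread.  Daytime and
nighttime indicators are the overall series ±(6.0 / 5.5) °C with
child-level jitter and daily noise.  Under these defaults the population
90th percentile of daily overall temperature is 20.6 °C — the same
headline threshold the exposure definition quotes — and the 10th
percentile (cold threshold) is 3.1 °C.

*Covariates.*  Ten baseline covariates (binary sex, binary exposure
flag, six standard-normal variables, and three whose means track the
enrollment wave — the season/covariate confounding channel, strength
0.5).  In addition the covariate table carries quantities any analyst
of such a cohort can compute from the calendar and weather normals:
season-of-conception (sin/cos), the local climate offset, and the
climatological expected number of hot days per 10-week period.  These
are what make the exposure process quasi-random given measured
covariates: without them the seasonal phase is a latent common cause of
the spike counts in every period and no estimator conditioning only on
counts could be consistent.

*Outcome.*  The latent log score is
`alpha0 + W·beta − Σ_t gamma_t A_t − Σ_t delta_t C_t + eps`, with
`gamma_t = 0.008` per heat spike, `delta_t = 0.006` per cold spike,
`alpha0 = 4.35`, and `eps ~ N(0, 0.2²)`; the integer word score is the
clipped, rounded inverse of the log(x+1) transform and the analysed
outcome is `log(score + 1)`.  The ceiling at 100 words binds for ~8% of
children — a deliberate, realistic source of nonlinearity.  `gamma` is
sized so that a 3 °C shift lowers the population log-mean by about
0.10, the order of magnitude of reported 3 °C effects, making power
checks realistic.

*Ground truth.*  `true_policy_mean` simulates fresh children, applies
the shift to the daily weather (all indicators move together), re-counts
spikes at the structural thresholds, and evaluates the structural
outcome equation — never the estimator.  Factual and counterfactual
outcomes share noise draws, so the Monte-Carlo SE of theta reflects only
the paired difference.  Because the shift moves the whole weather, the
truth depends on the policy only through `k`; the overall-indicator
analysis is the correctly specified one, and daytime/nighttime analyses
use proxy exposures (their direction is validated, not their exact
value).

*What the generator does not emulate.*  Real geography and residential
mobility; covariate marginals of an actual cohort; missing data (the
synthetic tables are complete — the mean/mode imputation utility is for
external data and is deliberately not a chained-equations procedure);
exposure-affected confounding (cold counts are functions of the same
exogenous weather, so the time-varying confounder is never itself
affected by earlier exposure — a documented simplification relative to
fully general longitudinal settings).  Passing tests on this cohort
therefore validate the estimator's mechanics and calibration under its
stated assumptions, not robustness to violations of them.

## Validation design and problem sizes

- Spike counting is checked against an independent brute-force run
  enumerator on 1,000 random 840-day series.
- A single-period discrete instance (binary W, exposure in {0,1,2},
  linear outcome mean, deterministic shift `d(a) = min(a+1, 2)`) has
  exhaustively enumerable truth and analytic density ratios; TMLE,
  the classification ratios, and both double-robustness degradations
  (mean-only outcome model with analytic ratios; identity ratios with
  the true model class in the library) are validated there at n = 5,000.
- Parameter recovery runs 20 seeded replicates at n = 2,000 with the
  fast library and three folds, at `k = 1` °C — the well-overlapped
  validation point.  At k = 2–3 the per-period ratios develop the heavy
  tails the truncation exists for (maxima of order 10–25), and at this
  sample size EIF Wald intervals are not expected to be calibrated
  there; those shifts are validated for sign and monotonicity instead.
- The null shift (k = 0) must return theta ≈ 0 exactly and per-period
  ratio means ≈ 1 (the stabilized-weight property).

Replicate counts and sample sizes are the package's chosen problem
sizes for desk-scale validation; the generator's defaults above are the
frozen study conditions.

## Numerical conventions

- Quantiles: threshold resolution interpolates linearly between order
  statistics; ratio truncation caps at the lower order statistic (a cap
  that actually occurred).  Both are fixed for reproducibility.
- "Exceeds" is strict (>); ties at the threshold are measure-zero for
  continuous temperatures, the convention simply has to be fixed.
- A run straddling a period boundary counts toward a period only if its
  within-period segment has ≥ min_run days.
- Spike = one maximal run counted once regardless of length
  (run-counting rather than hot-day counting), consistent with a
  24–48 h "heat spike" definition; the cold confounder mirrors the heat
  definition at the 10th percentile with min_run = 2 — a convention
  choice, since no standard definition exists.
- Degenerate regression targets collapse the stack onto the mean
  learner with a warning; an all-zero NNLS solution does the same.
- All randomness flows from explicit integer seeds; identical seeds and
  configs reproduce cohorts, stacks, and results bit for bit.

## Known limitations

- EIF Wald intervals undercover at strong shifts (k ≥ 2) at n = 2,000;
  this is a property of weight-based inference under marginal overlap,
  not a defect of the implementation, and it motivates the reported
  truncation diagnostics.
- The natural-course TMLE reproduces the empirical mean by
  construction; it is a consistency check, not an independent estimate.
- No sequentially doubly robust estimator variant, no mediation, no
  stochastic shifts; one temperature series per child.
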