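# heatlmtp

Causal analysis of ambient heat exposure and early-childhood language
development with **longitudinal modified treatment policies (LMTP)**.

Epidemiologists studying climate and child development increasingly ask
policy-shaped questions: *what would the population's language scores
have been had every day of each child's pre- and postnatal life been
k degrees warmer?*  This package implements that analysis end to end
for a birth-cohort design:

- **Exposure construction** — daily temperature series (overall /
  daytime / nighttime indicators) over a 120-week calendar (gestation
  weeks 1–30, postnatal weeks 1–90) are reduced to per-period **heat
  spike** counts: maximal runs of ≥ 2 consecutive days above a high
  percentile threshold, counted within each of 12 ten-week periods,
  with a mirrored cold-spike count as a time-varying confounder.
- **Shift interventions** — counterfactual exposures arise from the
  additive shift `d(Temp, k) = Temp + k`, k ∈ {1, 2, 3} °C; the causal
  parameter is `θ = E[Y^d] − E[Y]` on the `log(score + 1)` scale of a
  0–100 vocabulary-production score.
- **Density ratios by classification** — per-period ratios of
  counterfactual to factual exposure densities given the full history
  (the longitudinal analogue of stabilized weights), estimated with the
  classification trick and truncated at the 99.9th percentile.
- **Sequential-regression TMLE** — doubly robust targeted estimation of
  `E[Y^d]`, with intercept-only logistic fluctuations weighted by the
  cumulative ratios, and Wald inference from the efficient influence
  function (EIF).
- **SuperLearner-style stacking** — cross-validated convex combinations
  of linear, penalized, spline, forest, and gradient-boosting learners
  for every nuisance regression.
- **Synthetic birth cohort with known truth** — seasonal AR(1) weather,
  enrollment-wave confounding, and a structural outcome equation whose
  counterfactual means are computable exactly by Monte Carlo, so the
  whole pipeline can be validated for bias and CI coverage.

See `docs/methods.md` for the model, estimator, and design choices.

## Worked example

Simulate a cohort, run one warming scenario, and query the ground
truth:

```bash
heatlmtp simulate --seed 11 --n 2000 --out scratch/cohort
heatlmtp run --cohort-dir scratch/cohort --indicator overall \
    --percentile 0.9 --shift 3 --folds 3 --seed 1 --out scratch/results
heatlmtp truth --shift 3 --seed 11 --replicates 60000
```

The `run` step prints the results row (abridged):

```
indicator  percentile      k  threshold  psi_natural  psi_shift   theta  se_theta  ci_low  ci_high  p_value  bt_natural  bt_shift  ratio_max
  overall      0.9000 3.0000    20.5940       4.1282     4.0649 -0.0633    0.0121 -0.0870  -0.0396   0.0000     61.0686   57.2604    13.2011
```

and `truth` reports the Monte-Carlo oracle for the same policy:

```json
{"k": 3.0, "true_theta": -0.0947, "mc_standard_error": 0.00018, ...}
```

Reading: under the natural course the mean log score is 4.13 (≈ 61
words after back-transforming with `exp(x) − 1`); under +3 °C the
estimated mean drops by θ̂ = −0.063 log units (≈ 6% fewer words, ≈ 57
words), with a 95% CI excluding zero.  The generator's exact
counterfactual truth is −0.095: the estimate has the right sign and
order of magnitude but is conservatively attenuated at this strong
shift, where the density ratios are heavy-tailed (max ≈ 13 here) — the
regime the truncation diagnostics exist for.  At the well-overlapped
+1 °C shift the estimator is unbiased with calibrated intervals (19/20
coverage over seeded replicates; see `docs/methods.md` and the test
suite).

The same pipeline is available as a library:

```python
from heatlmtp import CohortConfig, ScenarioGrid, generate_cohort, run_grid

cohort = generate_cohort(CohortConfig(n_children=2000, seed=11))
grid = ScenarioGrid(indicators=("overall",), percentiles=(0.90,),
                    shifts=(1.0, 2.0, 3.0), seed=1, folds=3)
results = run_grid(cohort, grid)   # one audited row per scenario
```

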