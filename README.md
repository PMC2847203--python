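# bayesce

Bayesian multi-state cost-effectiveness modelling with structural
uncertainty. The package fits discrete-time (daily) multi-state transition
models to yearly-aggregated multinomial transition counts by MCMC,
propagates the full joint parameter uncertainty into lifetime expected
costs and QALYs (one-stage probabilistic sensitivity analysis), assesses
each candidate model structure by predictive criteria (harmonic-mean
CPO / pseudo-marginal-likelihood and DIC), converts those criteria into
model selection probabilities with a Bayesian bootstrap, and mixes the
per-model posteriors into a model-averaged analysis.

## Modules

| module | what it does |
|---|---|
| `bayesce.model_spec` | state spaces, covariates, coefficient tying/zeroing constraints, the M1–M10 variant factory, transition probabilities |
| `bayesce.inference` | multinomial likelihood, normal priors, adaptive Metropolis-within-Gibbs sampler (numba), posterior summaries |
| `bayesce.cost_effectiveness` | daily cohort propagation with age-updated transition matrices, discounted cost/QALY accumulation, ICER / INB / PCE |
| `bayesce.assessment` | per-observation log-CPO (harmonic mean), log-PML, DIC with per-observation decomposition |
| `bayesce.averaging` | flat-Dirichlet bootstrap replicates of log-PML/DIC, model selection probabilities, mixture model averaging |
| `bayesce.synthetic_data` | study-like synthetic cohorts with known ground truth |
| `bayesce.io_cli` | `bayesce` command-line pipeline and reporting |

## Command-line pipeline

```sh
# synthetic cohort under base-case (M1) ground truth
bayesce simulate --model M1 --n-patients 250 --seed 1 --out data.csv

# fit two candidate structures
bayesce fit --data data.csv --model M1 --profile test --seed 1 --out m1.csv
bayesce fit --data data.csv --model M7 --profile test --seed 1 --out m7.csv

# lifetime cost-effectiveness per posterior draw (both treatment arms)
bayesce ce --sample m1.csv --model M1 --out ce1.csv
bayesce ce --sample m7.csv --model M7 --out ce7.csv

# predictive adequacy (log-CPO, DIC decomposition)
bayesce assess --sample m1.csv --data data.csv --model M1 --out a1.csv
bayesce assess --sample m7.csv --data data.csv --model M7 --out a7.csv

# bootstrap selection probabilities and the summary table
bayesce average --assessment a1.csv --assessment a7.csv --seed 1 --out w.csv
bayesce report --assessment a1.csv --assessment a7.csv \
               --ce ce1.csv --ce ce7.csv --wtp 20000 --seed 1 --out report.csv
```

The report has one row per model (plug-in deviance, p_D, DIC, −2 log PML,
selection probabilities under both criteria, incremental cost/QALY with
95% intervals, ICER, probability of cost-effectiveness) plus two
model-average rows. `--profile full` switches the sampler to the full
30000-iteration / 5000 burn-in run (25000 kept draws); the default `test`
profile is reduced for fast iteration.

Model structures beyond the built-in labels M1–M10 can be given as YAML
files with explicit tie/zero constraint lists (see
`bayesce.model_spec.config_to_dict` for the schema; round-trips are
lossless).

## Conventions worth knowing

- States are 1-based everywhere; state 1 is the reference destination of
  every transient row (it is also the starting state for cohort
  propagation); the last state is absorbing death.
- The treatment covariate is named `aad` (1 = drug arm, 0 = device arm) so
  that its death-row coefficient matches the informative prior
  N(0.414, 0.16²); the cost schedule indexes arms as u=0 (drugs) and
  u=1 (device).
- Age enters either as piecewise indicators (60–70, ≥70) or as polynomial
  terms of (age − 63)/10; the centering/scaling constants live in the
  covariate spec, so serialized models are self-describing.
- A year is 365 days; the annual discount rate converts to a daily factor
  (1+r)^(−1/365); the initial cost is undiscounted at day 0.
- Per-observation quantities (CPO, DIC_i) use one (patient, year,
  from-state) multinomial row as the observation unit;
  `FitAssessment.grouped_by_patient()` switches to per-patient grouping.
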