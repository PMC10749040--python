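# racemix

Models of mass-participation race times in which natal sex is a *latent*
binary covariate: each record carries a known probability of being natal male,
derived from the registered category, a partial lookup of known sexes, or the
sex ratio of the athlete's given name among US births in the two candidate
birth years. The package provides:

- **`racemix.synth`** — synthetic race results, SSA-layout name-frequency
  tables and partial sex lookups, with the ground truth retained for recovery
  tests.
- **`racemix.names`** — natal-sex probability assignment
  (declared > lookup > name model), cross-validation of the name model against
  lookup labels, and an optional uncertainty widening toward 0.5.
- **`racemix.crossrace`** — per-event no-intercept calibration against the
  marathon with relative-residual trimming, event ranking by "marathon
  correlation", one-record-per-athlete selection and an 11-hour
  predicted-time outlier filter.
- **`racemix.latent`** — the four log-time linear models with
  latent-dependent covariates (`nb_predictor`, `is_nbm`, `is_nbf`, `is_nb`),
  fitted by EM on the marginal likelihood over both completions of the latent
  sex; parametric-bootstrap Monte Carlo p-values; effect sizes as
  `100·(exp(β)−1)` percent; residual Q-Q data.
- **`racemix.pipeline` / `racemix.cli`** — power analysis and end-to-end
  orchestration behind a `racemix` command.

## CLI

```sh
# sample size for a two-sample one-tailed t-test (prints 138)
racemix power --delta 24.6 --sd 58 --power 0.8 --alpha 0.05 --one-tailed

# synthetic bundle -> cross-race dataset -> probabilities -> model fits
racemix simulate --out sim --seed 1 --n-athletes 2000 --frac-nonbinary 0.02
racemix build --results sim/results.csv --out built
racemix assign-sex --data built/cross_race.csv --names sim/names \
    --lookup sim/lookup.csv --out assigned
racemix fit --data assigned/cross_race_assigned.csv --out fits \
    --models 1,2,3,4 --n-sims 1000 --seed 1
```

`build` writes the cross-race dataset plus a three-line construction summary
and per-event calibrations; `assign-sex` writes the assigned dataset, a
resolution summary for non-binary athletes and a lookup/name-model
cross-validation report; `fit` writes one coefficient table per model
(Parameter, Coefficient, Effect size, one/two-tailed Monte Carlo p-values,
significance stars) and two-column Q-Q CSVs. All steps are deterministic
under a fixed seed. Defaults (trim keep-fraction 0.98, 11-hour cutoff,
100 000 bootstrap samples) reproduce the reference analysis settings; use
`--n-sims` to scale the bootstrap down.

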