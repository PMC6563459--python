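# levelcast

Bayesian local-level structural time-series now/forecasting for small-area
annual health-event counts.

Each area gets an independent state-space model: a Gaussian random-walk level
plus a static regression on demographic covariates (total population and
eight age strata) under a spike-and-slab prior. Posteriors are Gibbs-sampled
(forward-filtering backward-sampling for the level, stochastic search
variable selection for the regression), posterior-predictive now/forecasts
are summarized with 95% equal-tailed credible intervals, chains are gated by
Raftery–Lewis, Geweke, Heidelberger–Welch and Durbin–Watson diagnostics, and
per-area predictive draws aggregate to regional / cluster / national totals
with crude rates per 1,000 population.

## Modules

| module | role |
|---|---|
| `levelcast.state_space` | Kalman filter, FFBS draws, random-walk level simulation |
| `levelcast.spike_slab` | spike-and-slab prior construction, collapsed marginal likelihood, SSVS Gibbs sweeps, conditional (β, σ²) draws |
| `levelcast.fit` | per-area three-block Gibbs orchestration, burn-in, retained draws |
| `levelcast.predict` | posterior-predictive forecasting, BMA inclusion probabilities |
| `levelcast.diagnostics` | the four MCMC/residual gates with pass thresholds |
| `levelcast.validation` | rolling nowcast windows, percent errors, calibration regression, random-walk baseline |
| `levelcast.geography` | area hierarchy, draw aggregation, crude rates and rate changes |
| `levelcast.synthetic_data` | panel generator with known ground truth |
| `levelcast.cli_io` | CSV readers/writers, YAML config, subcommand CLI, pipeline |

## CLI

```bash
# generate a synthetic panel with known truth
levelcast simulate --seed 1 --out panel.csv

# full pipeline: simulate/read -> fit -> diagnose -> validate -> forecast -> aggregate
levelcast run --config config.yaml --seed 1 --out-dir out/
```

A config file is a flat YAML document:

```yaml
seed: 1
panel: null          # path to a panel CSV; null = simulate
geography: null      # optional area_id,region,supergroup,group,subgroup CSV
exclusions: []       # area ids dropped before modelling
horizon: 5
fit:
  n_iterations: 20000
  burn_in_fraction: 0.10
synthetic:
  n_areas: 20
```

Interchange formats are plain CSV with mandated headers; see
`levelcast.cli_io` docstrings. Outputs carry a config hash and the seed, and
reruns are byte-identical.

## Notes

- Sampler defaults: 20,000 iterations, 10% burn-in, expected model size 5 of
  9 covariates, expected explained variance 70%, level-innovation SD prior
  centred at 1% of the series SD and truncated at 150% of it.
- Quantiles use linear interpolation (type-7); error summaries report the
  median, IQR, range and the count of areas within ±10%.
- All randomness flows through explicit seeded `numpy.random.Generator`
  streams; identical inputs and seed give bitwise-identical draws.
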