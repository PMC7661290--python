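# fishpass

Density-dependent dam-passage analysis for upstream-migrating fish.

The package decomposes dam passage into three stages — *finding* a fishway
entrance after entering the tailrace, *committing* (passing fully on the
first attempt), and transiting the *fishway* itself — and models them with
counting-process proportional-hazards models (time-varying temperature,
spill, diel and daily-count covariates) and logistic regression. Because
daily counts are themselves produced by passage events, naive inference on
the count (density) coefficient suffers reverse causality; the central
inferential tool here is a **parametric-bootstrap null test**: simulate
full datasets from an AICc-selected null model containing no count
covariate, refit the full model with the observed counts attached, and use
the refitted count coefficients as the null distribution. Fitted models
feed density-scenario simulations (counts rescaled by a factor 0–2,
replicate cohorts simulated by cumulative-hazard inversion).

A synthetic telemetry generator with known ground truth is included and is
first-class: it drives the calibration, power, coverage and end-to-end
acceptance tests.

## Layout

| module | contents |
|---|---|
| `fishpass.synthetic` | ground-truth worlds: environment series, PH-driven fish histories, Bernoulli commit outcomes, observer counts derived *from* passage (lag + overdispersion) |
| `fishpass.survival` | risk-set construction, Breslow partial-likelihood Newton–Raphson fitter, Breslow baseline, event-time simulation, PH diagnostic |
| `fishpass.commit` | commit tables and IRLS logistic fits, commit-rate prediction under density factors |
| `fishpass.bootstrap` | null-model selection, null-distribution test, full-model percentile CIs |
| `fishpass.scenario` | density-scenario simulation and contrasts |
| `fishpass.pipeline` | model splitting, orchestration, reports |
| `fishpass.tables`, `fishpass.cli` | CSV/JSON I/O and the command line |

## Command line

```sh
fishpass simulate --truth truth.yaml --out-dir world/
fishpass fit      --fish world/fish_events.csv --covariates world/covariates.csv \
                  --counts world/daily_counts.csv --stage finding --out fit.json
fishpass analyze  --fish ... --covariates ... --counts ... \
                  --config analysis.yaml --out-dir results/
fishpass scenario --fish ... --covariates ... --counts ... \
                  --factors 0,0.5,1,1.5,2 --out curves.csv
fishpass report   --report results/report.json
```

`truth.yaml` mirrors `fishpass.SimulationTruth`; `analysis.yaml` mirrors
`fishpass.AnalysisConfig` (see `fishpass.default_split_config()` for the
standard 13-model split by species / process / dam / run / fishway).

All timestamps are hours from a per-season origin; daily covariates are
step functions on calendar days; risk intervals are half-open `(start,
stop]` with left-evaluated covariates.

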