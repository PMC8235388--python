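# nutrisk

A stochastic multi-region world-trade equilibrium pipeline for measuring
"nutrition at risk": the worst-tail loss of household wheat consumption
under Monte Carlo productivity shocks and export-quota scenarios,
expressed as a percentage of a population's annual nutrient requirements.

The pipeline is fully synthetic and self-contained: a generator builds a
balanced multi-region social accounting matrix (SAM), yield histories
with a known ARMA data-generating process, and nutrition tables with
known ground truth, so every downstream stage is testable without any
external data.

## Stages

| module | role |
| --- | --- |
| `nutrisk.synthetic_world` | balanced SAMs, yield series, nutrition tables |
| `nutrisk.yield_volatility` | standardize, ARIMA fit (AIC selection), residual SD |
| `nutrisk.sam_calibration` | CES/CET/Leontief/Cobb-Douglas calibration, quota sizing |
| `nutrisk.cge_core` | static equilibrium system, damped-Newton solver, quotas |
| `nutrisk.shock_engine` | seeded shock matrices, scenario batches (Reference/Y/YQ) |
| `nutrisk.nutrition_risk` | nutrient supply/requirements, VaR, NAR, return periods |
| `nutrisk.scenario_cli` | config, orchestration, manifests, CLI |

Model structure per region: Leontief gross output over intermediate
composites and a CES value-added bundle (mobile labor plus a
sector-specific factor, fully employed); a Hicks-neutral productivity
shifter on the wheat sector (floored at 0.3); CET allocation between
domestic sales and bilaterally distributed exports; Armington CES
aggregation of domestic goods with bilaterally sourced imports (wheat
elasticity 4.45); two-stage household demand (CES food nest with
elasticity 0.1 under a Cobb-Douglas top); savings-driven investment and
fixed foreign savings. Export quotas are solved by active-set iteration
with rent wedges accruing to the exporting household.

## CLI

```sh
nutrisk run --config examples/config_example.yaml
nutrisk generate-world --config examples/config_example.yaml --out world/
nutrisk fit-volatility --yields yields.csv --out volatility.csv
nutrisk report --run-dir out --scenario YQ -p 0.05
```

`run` executes all configured scenarios end to end and writes CSV tables
(SAM, volatility fits, shock matrix, per-draw consumption distributions,
contribution shares, NAR tables, return-period amplification) plus a
`manifest.json` with the seed, the config hash and a checksum per
output; re-running the same config reproduces the outputs byte for byte.
Exit codes: 0 success, 2 configuration error, 3 solver failure.

The example config uses 1000 draws per scenario; reduce `n_draws` for a
quick desk run.

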