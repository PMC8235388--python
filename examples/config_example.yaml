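# Example end-to-end run configuration.
#
# Every study constant appears explicitly here rather than hiding behind a
# default:
#   4.45  -- Armington substitution elasticity for wheat
#   0.1   -- CES elasticity of the household food nest
#   0.3   -- floor on the multiplicative yield shifter
#   1000  -- Monte Carlo draws per scenario
#   0.5   -- export-quota fraction of baseline bilateral exports
#   0.05 / 0.01 -- value-at-risk tail probabilities (1-in-20 / 1-in-100 years)

world:
  regions: [exporter, importer, third]
  sectors: [wheat, otherfood, foodproc, nonfood]
  wheat_sector: wheat
  food_sectors: [wheat, otherfood, foodproc]
  heterogeneity: 0.15
  export_share_overrides:
    exporter/wheat: 0.5
    importer/wheat: 0.01
    third/wheat: 0.05
  savings_rate: {exporter: 0.45, importer: 0.12, third: 0.18}
  armington_elasticity: {wheat: 4.45, "*": 2.0}
  food_nest_elasticity: 0.1
  seed: 1

scenarios: [Reference, Y, YQ]
n_draws: 1000          # reduce (e.g. 100) for a quick desk run
seed: 42
floor: 0.3

quota:
  exporters: [exporter]
  fraction: 0.5
  mode: bilateral      # or "aggregate" for a cap on total wheat exports

var_probabilities: [0.05, 0.01]

# volatility source: generate synthetic yield histories (25 years) and fit
# the ARIMA pipeline; alternatively give `sigmas` directly or a `yield_csv`
yield_dgp:
  exporter: {sd: 0.16}
  importer: {sd: 0.37}
  third: {sd: 0.08}
yield_n_years: 25

output_dir: out
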