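# Example analysis configuration for `demosurv run-all --config examples/config.yaml`
study_start: "2003-01-01"
study_end: "2018-12-31"
period_years: [2003, 2007, 2011, 2015]   # four 4-year analysis periods
rule: standard                            # or: madimah
seed: 1
n_baseline: 10000
outdir: runs/demo
stages: [rates, lifetable, season, heterogeneity]
# reference_structure: path/to/ref.csv   # columns age_band,sex,weight
# sim_overrides:                         # any SimConfig field, e.g.:
#   outmigration_rate: 0.1
#   seasonal_amplitude: 1.8
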