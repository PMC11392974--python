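# Bundled demo: simulated default survey (60 sites, 4 seasons) with a
# reduced MCMC budget. `occudyn run --config configs/demo.yaml` completes in
# a few minutes on one CPU and writes per-species report CSVs.
design:
  n_sites: 60
species:
  - name: demo
    seasons: all
candidates:
  strict_univariate: false
mcmc:
  n_chains: 3
  n_iter: 3000
  n_burn: 1000
  n_average_draws: 4000
simulate:
  dropout_rate: 0.05
seed: 20
output_dir: null
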