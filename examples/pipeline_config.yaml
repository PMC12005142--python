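# Demo config for `pbscan run-all --config examples/pipeline_config.yaml --out outdir`
# Simulates a 3-population low-coverage dataset with an implanted sweep and
# runs filtering, SFS/FST estimation, the PBS scan and structure inference.
seed: 1

simulate:
  n_sites: 8000
  chrom_length: 8000000
  n_individuals: [33, 25, 25]
  drift: [0.068, 0.020, 0.012]   # pairwise FST ~ (c_i + c_j)/2
  mean_depth: 2.0
  error_rate: 0.01
  sweep: {population: 0, start: 3000001, end: 3100000, delta: 0.8}

sfs:
  max_iter: 100
  tol: 1.0e-5

scan:
  window: 20000        # desk-scale resolution; use 50000/10000 at genome scale
  step: 10000
  top_fraction: 0.01   # desk-scale tail; 0.001 at genome scale
  min_windows: 6
  merge_distance: 1000000

structure:
  K: 3
  n_restarts: 3
  max_iter: 300
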