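# Demo pipeline configuration: simulate a 6-patient cohort and run every
# stage. All thresholds shown with their defaults.
out: ibcpipe_run
simulate:
  n_patients: 6
  seed: 1
  purity_range: [0.2, 0.9]
  depth_mean: 400
  wgd_probability: 0.7
consensus:
  min_callers: 2
  min_vaf: 0.05
cna:
  n_simulations: 2000
  alpha: 0.05
  seed: 1
signatures:
  weight_floor: 0.06
  error_tolerance: 0.001
clonal:
  iterations: 1200
  burn_in: 600
  concentration: 1.0
  seed: 7
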