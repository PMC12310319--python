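# Checked-in analysis defaults; every stage parameter can be overridden
# in a run config.
seed: 0
describe:
  correction: false
ising:
  gamma: 0.5
  rule: and
  n_lambda: 100
  lambda_min_ratio: 0.01
  standardize: false
clpn:
  folds: 10
  rule: 1se
  n_lambda: 100
  lambda_min_ratio: 0.01
  stratify: true
  standardize: false
stability:
  boots: 1000
  grid_max: 0.75
  grid_step: 0.05
  threshold_r: 0.7
  confidence: 0.95
  method: pearson
compare:
  perms: 1000
  paired: true
simulate:
  n: 1000
  preset_seed: 0
  burn_in: 1000
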