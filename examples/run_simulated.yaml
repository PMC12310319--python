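# Small simulated end-to-end run (finishes in ~1 minute on one core).
seed: 1
input:
  simulate:
    n: 1000
ising:
  n_lambda: 50
  lambda_min_ratio: 0.05
clpn:
  n_lambda: 50
  lambda_min_ratio: 0.05
stability:
  boots: 50
  grid_step: 0.25
  grid_max: 0.75
compare:
  perms: 100
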