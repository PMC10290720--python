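# Knowledge-transfer run on the default class-non-IID synthetic task.
method: privatekt
seed: 1
rounds: 30
n_clients: 10
epsilon: 5.0
k: 2
data:
  n_samples: 2000
  n_classes: 10
  n_features: 8
  separation: 3.0
  pool_fraction: 0.2
  n_test: 2000
partition:
  scheme: class_noniid
  alpha: 0.5
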