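# Default run configuration: reproduces the studied plant's dataset
# statistics, the three-model soft-sensor comparison, the entropy
# analysis and the 12-week assisted-operation campaign.
seed: 42

generator:
  n: 10000
  fault_rate: 0.023
  seasonal_temp_amplitude: 1.2

preprocess:
  split_mode: chronological
  core_threshold: 0.40

models:
  svm:
    C: 10.0
    gamma: 0.05
    epsilon: 0.1
  rf:
    n_trees: 100
    max_depth: 18
    mtry: 2
  ann:
    hidden_sizes: [128, 64]
    learning_rate: 0.001
    batch_size: 64
    l2_lambda: 0.0001
    max_epochs: 500
    early_stop_patience: 20

entropy:
  n_perm: 10
  estimator: plug_in
  state_window: 24h

operation:
  weeks: 12
  shock_rate_per_hour: 0.125
  shock_sd: 3.8
  unpredictable_sd: 10.5
  seasonal_amplitude: 2.0
  gain: 1.0

tea:
  capex: 500000.0
  operating_saving: 13.5
  capacity: 100.0
  discount_rate: 0.08
  lifetime: 10
  baseline_energy_intensity: 100.0
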