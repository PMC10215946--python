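# Default pipeline configuration. Every value that the study protocol fixes
# is fixed here: 30 trials/class, 10 s trials, 30 EEG + 36 fNIRS channels,
# 10 whales, 50 iterations, 80/20 split, 10 runs.
simulate:
  n_trials_per_class: 30
  n_eeg_channels: 30
  n_fnirs_channels: 36
  trial_duration: 10.0
  fs_eeg: 200.0
  fs_fnirs: 10.0
  eeg_effect: 0.5
  fnirs_effect: 0.8
  informative_eeg_channels: [8, 23]
  informative_fnirs_channels: [2, 19]
optimizer:
  n_whales: 10
  max_iter: 50
  pool_size: 20
  migration_rate: 0.2
  neighborhood_radius: 0.1
  transfer: sigmoid
  threshold: 0.5
wrapper:
  alpha: 0.99
  cv_folds: 5
  svm_c: 1.0
protocol:
  train_fraction: 0.8
  n_runs: 10
  resplit: true
  leaky_normalization: false
  methods: [none, ewoa]
seed: 7
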