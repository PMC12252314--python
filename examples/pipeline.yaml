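# Desk-scale end-to-end run: simulate -> preprocess -> train-torsion ->
# estimate -> train-detector -> detect -> evaluate.
# Every stochastic stage carries an explicit seed; unknown keys are rejected.
scene:
  noise_sd: 2.0
torsion:
  n_scenes: 4
  n_train_samples: 400
  n_val_samples: 80
  max_epochs: 2
  batch_size: 32
detector:
  n_series_per_class: 40
  window_size: 3
  max_epochs: 20
evaluation:
  n_series_per_class: 2
  duration: 5.0
seeds:
  simulate: 11
  torsion: 12
  detector: 13
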