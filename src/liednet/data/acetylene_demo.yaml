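# Demo retrieval run: acetylene (H-C#C-H), synthetic experiment.
# Labels are (R_CC, R_CH) in Angstrom; the database samples the parameter
# box uniformly and maps are simulated with the screened-Born IAM.
molecule: acetylene
database:
  mode: parameter-grid
  parameters:
    - [R_CC, 1.00, 1.40, uniform]
    - [R_CH, 0.86, 1.26, uniform]
  count: 8000
  seed: 11
grid:
  n_energies: 32
  n_angles: 32
  energy_range: [50.0, 300.0]
  angle_range: [30.0, 180.0]
prep:
  fractions: [0.8, 0.1, 0.1]
  seed: 7
cnn:
  conv_layers: [[32, 5], [32, 3], [32, 3]]
  fc_depth: 3
  fc_width: 64
  batch_size: 120
  learning_rate: 0.002
  lr_schedule: cosine
  epochs: 50
  batch_norm: true
  optimizer: adam
ensemble:
  k: 5
experiment:
  # hidden ground truth, off the equilibrium geometry but inside the ranges
  truth_labels: [1.23, 1.08]
  total_counts: 10000000
  seed: 1234
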