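# Demo retrieval run for the packaged 27-atom bicyclic ketone (C10H16O).
# The database deforms four chemically sensible atom groups (rigid shifts)
# plus a molecule-wide scale; labels are the Cartesian coordinates of seven
# tracked skeleton atoms (21 values, Angstrom).
#
# The group memberships below index into data/fenchone_synthetic.xyz and are
# a packaged example (carbonyl C=O, the gem-dimethyl pair, the bridgehead
# methyl, and the ethano bridge); adjust for other molecules.
molecule: fenchone_like
tracked_atoms: [0, 1, 3, 4, 5, 6, 9]
database:
  mode: group-deformation
  groups:
    - [3, 4]                      # carbonyl C=O
    - [0, 2, 11, 12, 13, 14, 15, 16]  # gem-dimethyl carbons + their hydrogens
    - [6, 17, 18, 19]             # bridgehead methyl
    - [7, 8, 20, 21, 22, 23]      # ethano bridge CH2-CH2
  shift_range: [-0.3, 0.3]
  global_scale: [0.9, 1.1]
  count: 5000
  seed: 21
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
  fc_width: 128
  n_pool: 2
  batch_size: 120
  learning_rate: 0.002
  lr_schedule: cosine
  epochs: 50
  batch_norm: true
  optimizer: adam
ensemble:
  k: 1
experiment:
  total_counts: 10000000
  seed: 1234
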