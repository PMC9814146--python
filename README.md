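# liednet

Retrieval of gas-phase molecular structure from laser-induced electron
diffraction (LIED) data with a convolutional neural network.

In LIED, an electron wavepacket is tunnel-ionized from a molecule by a strong
laser field, driven back, and elastically rescattered off its parent ion; the
molecular geometry is imprinted on the measured differential cross-section
(DCS) as a two-centre interference signal. Inverting that signal is hard:
classical template matching must precompute maps for every candidate
geometry, and the cost grows as n x 3^N for N atoms on an n-step grid —
about 1.45e9 CPU-hours for a 20-atom molecule at five steps and five minutes
per map. `liednet` takes the learning route instead: simulate a *coarse*
database of geometries, train a CNN regressor on the simulated maps, and let
the network interpolate to the measured (or synthetic) input.

The package is aimed at researchers in ultrafast diffraction imaging and
anyone studying CNN-based inversion of scattering data. It provides:

- **Forward model** — orientation-averaged elastic 2D-DCS maps over (return
  energy, rescattering angle) via the independent atomic model (IAM):
  `sigma_tot(q) = sum_i f_i^2 + sum_{i!=j} f_i f_j sinc(q R_ij)`, with
  self-contained screened-Born atomic amplitudes and a pluggable interface
  for tabulated ones.
- **Structure parametrisation** — label schemes mapping geometries to the
  regressed vectors (bond lengths/angles for small molecules, tracked-atom
  Cartesian coordinates for large ones) and database generators (parameter
  grids, uniform sampling, rigid atom-group shifts + global scale).
- **Regressor** — a statsmodels-style model object: `DCSRegressor(dataset,
  config).fit()` returns a results object with per-epoch mean-absolute-error
  (MAE) history, held-out test error, `summary()`, `predict()` and
  checkpointing. The network (3 conv blocks of 32 filters with batch norm
  and max pooling + a deep fully connected stack, quadratic cost, gradient
  descent / Adam) is implemented from scratch in NumPy and gradient-checked.
- **Error budget & evaluation** — ensemble retrieval (mean of k retrainings),
  model error from the test split, experimental error by propagating the
  +-sqrt(n) Poisson extrema of a counts map through the retrieval, Pearson
  self-consistency with bootstrap confidence intervals, and the brute-force
  scaling estimator.
- **Synthetic experiments** — Poisson-noised counts maps of a hidden
  ground-truth structure stand in for (unavailable) reaction-microscope
  data, enabling end-to-end parameter-recovery studies.

See `docs/methods.md` for the model details, parameter defaults and
limitations.

## Worked example

Train a regressor on a synthetic acetylene database and retrieve a hidden
structure from a Poisson-noised synthetic measurement:

```python
import liednet as ln
from liednet.model import CNNConfig, DCSRegressor

amp = ln.ScreenedBornAmplitudes()
grid = ln.default_grid(32, 32)                    # E_r 50-300 eV, theta_r 30-180 deg
scheme = ln.SymmetricLinearScheme()               # labels: (R_CC, R_CH) in Angstrom

# 8,000 geometries sampled uniformly over the label box
spec = ln.DeformationSpec(
    mode="parameter-grid", scheme=scheme,
    parameters=[("R_CC", 1.00, 1.40, "uniform"), ("R_CH", 0.86, 1.26, "uniform")],
    count=8000, seed=11)
db = ln.generate_database(spec)

# difference maps vs the equilibrium structure, split 80/10/10
ds = ln.assemble_dataset(db, ln.acetylene(), grid, amp, seed=7, scheme=scheme)

cfg = CNNConfig(fc_depth=3, fc_width=64, epochs=50, optimizer="adam",
                learning_rate=2e-3, lr_schedule="cosine", seed=0)
res = DCSRegressor(ds, cfg).fit()
print(res.summary())

# synthetic "measurement": hidden truth + counting noise at 1e7 counts
truth = scheme.structure([1.23, 1.08])
counts = ln.poissonize(ln.dcs_map(truth, amp, grid), 10_000_000, seed=1234)
ref = ln.dcs_map(ln.acetylene(), amp, grid)
from liednet.prep import counts_to_map
measured = ln.difference_map(counts_to_map(counts), ref)
print("retrieved labels:", res.predict(measured))
r = ln.self_consistency(counts.counts,
                        ln.dcs_map(scheme.structure(res.predict(measured)), amp, grid).values)
print("self-consistency Pearson r:", round(r, 4))
```

This prints (50 epochs, a few minutes on one CPU core):

```
                      DCS Regressor Results
================================================================
Input grid:        32 x 32 (return energy x rescattering angle)
Labels:            2
Samples:           8000 (train 6400 / val 800 / test 800)
Conv layers:       [(32, 5), (32, 3), (32, 3)]
FC stack:          depth 3, width 64
Parameters:        36610
Optimizer:         adam, alpha=0.002, batch=120, epochs=50, seed=0
----------------------------------------------------------------
Final train MAE:   0.00290
Final val MAE:     0.00284
Test MAE:          0.00285
----------------------------------------------------------------
Test MAE per label:
  R_CC             0.00277
  R_CH             0.00293
================================================================
retrieved labels: [1.17678757 1.13210088]
self-consistency Pearson r: 0.9999
```

Training, validation and test MAE agree at ~0.003 Angstrom (no
overfitting): on *noiseless* inputs the network interpolates the label box
to a few thousandths of an Angstrom. The noisy retrieval is further from
the hidden truth (1.23, 1.08) — about 0.05 A here — because at 1e7 total
counts the per-pixel Poisson noise is comparable to the interference-fringe
amplitude in the difference map; that counting-statistics uncertainty is
exactly what the ensemble error budget (`liednet.evaluate.error_budget`)
attaches to a retrieval, while the map recomputed from the prediction still
correlates with the measurement at r > 0.99.

The same pipeline is available from the shell via YAML configs (packaged
demos in `src/liednet/data/`):

```sh
liednet retrieve path/to/run.yaml --out results/run1 -v   # full ensemble retrieval
liednet synthetic-exp path/to/run.yaml --out results/rec --tolerance 0.05
liednet estimate-scaling -n 5 -N 20 -t 5                  # brute-force cost
```

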