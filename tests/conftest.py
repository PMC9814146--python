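"""Shared fixtures: small structures, grids, and session-scoped trained models.

The expensive end-to-end trainings (used by the acceptance tests) are
session-scoped so each pipeline runs exactly once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import liednet as ln
from liednet.model import CNNConfig, DCSRegressor

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def amplitudes():
    return ln.ScreenedBornAmplitudes()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_grid():
    return ln.default_grid(8, 8)


@pytest.fixture(scope="session")
def acetylene_structure():
    return ln.acetylene()


def random_structure(rng, n_atoms, elements=("H", "C", "O", "S")):
    """A random small molecule with coordinates in a ~3 A box."""
    els = list(rng.choice(elements, size=n_atoms))
    coords = rng.uniform(-1.5, 1.5, size=(n_atoms, 3))
    return ln.MolecularStructure.from_arrays(els, coords, name="random")


def random_rotation(rng):
    """A uniformly random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# Session-scoped pipelines (shared by acceptance + a few integration tests)
# ---------------------------------------------------------------------------

C2H2_DB = dict(r_cc=(1.00, 1.40), r_ch=(0.86, 1.26), count=8000, seed=11)
C2H2_GRID = (32, 32)
C2H2_CNN = dict(fc_depth=3, fc_width=64, epochs=50, optimizer="adam",
                learning_rate=2e-3, lr_schedule="cosine", seed=0)


@pytest.fixture(scope="session")
def c2h2_dataset(amplitudes):
    """Synthetic acetylene difference-map dataset: 8,000 structures, 80/10/10."""
    spec = ln.DeformationSpec(
        mode="parameter-grid", scheme=ln.SymmetricLinearScheme(),
        parameters=[("R_CC", *C2H2_DB["r_cc"], "uniform"),
                    ("R_CH", *C2H2_DB["r_ch"], "uniform")],
        count=C2H2_DB["count"], seed=C2H2_DB["seed"])
    db = ln.generate_database(spec)
    return ln.assemble_dataset(db, ln.acetylene(), ln.default_grid(*C2H2_GRID),
                               amplitudes, seed=7,
                               scheme=ln.SymmetricLinearScheme())


@pytest.fixture(scope="session")
def c2h2_results(c2h2_dataset):
    """The trained acetylene regressor (>= 50 epochs)."""
    return DCSRegressor(c2h2_dataset, CNNConfig(**C2H2_CNN)).fit()


@pytest.fixture(scope="session")
def fenchone_run(amplitudes):
    """Group-deformation pipeline for the packaged 27-atom bicyclic ketone."""
    base = ln.fenchone_like()
    groups = [[3, 4], [0, 2, 11, 12, 13, 14, 15, 16],
              [6, 17, 18, 19], [7, 8, 20, 21, 22, 23]]
    spec = ln.DeformationSpec(mode="group-deformation", base_structure=base,
                              groups=groups, shift_range=(-0.3, 0.3),
                              global_scale=(0.9, 1.1), count=5000, seed=21)
    scheme = ln.CartesianSubsetScheme(base, [0, 1, 3, 4, 5, 6, 9])
    db = ln.generate_database(spec, scheme=scheme)
    ds = ln.assemble_dataset(db, base, ln.default_grid(32, 32), amplitudes,
                             seed=7, scheme=scheme)
    res = DCSRegressor(ds, CNNConfig(fc_depth=3, fc_width=128, n_pool=2,
                                     epochs=50, optimizer="adam",
                                     learning_rate=2e-3, lr_schedule="cosine",
                                     seed=0)).fit()
    return ds, res
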