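"""IAM scattering: kinematics, amplitudes, maps, and their invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import liednet as ln
from liednet.constants import BOHR_PER_ANGSTROM, HARTREE_EV
from liednet.scattering import export_csv, load_map, save_map

from conftest import random_rotation, random_structure


class TestMomentumTransfer:
    def test_forward_scattering_is_zero(self):
        assert ln.momentum_transfer(100.0, 0.0) == 0.0

    def test_backscattering_closed_form(self):
        # q = 2 sqrt(2 E / Hartree) at 180 degrees
        assert ln.momentum_transfer(100.0, 180.0) == pytest.approx(5.422126705, abs=1e-6)

    def test_sixty_degrees_equals_k(self):
        # sin(30 deg) = 1/2 so q = k
        k = np.sqrt(2 * 50.0 / HARTREE_EV)
        assert ln.momentum_transfer(50.0, 60.0) == pytest.approx(k, rel=1e-12)

    def test_nonpositive_energy_raises(self):
        with pytest.raises(ValueError):
            ln.momentum_transfer(0.0, 90.0)


class TestScreenedBornAmplitudes:
    def test_q0_closed_form(self, amplitudes):
        alpha1 = 1 / 0.88534
        assert amplitudes(1, 0.0) == pytest.approx(2 / alpha1**2, rel=1e-12)

    def test_hydrogen_at_q1(self, amplitudes):
        assert amplitudes(1, 1.0) == pytest.approx(0.8788149890, abs=1e-9)

    def test_rutherford_limit(self, amplitudes):
        q = 1e4
        for z in (1, 6, 16):
            assert amplitudes(z, q) == pytest.approx(2 * z / q**2, rel=1e-6)

    @given(z=st.sampled_from([1, 6, 8, 16]),
           q=st.floats(0.0, 50.0))
    @settings(max_examples=60, deadline=None)
    def test_positive_and_decreasing(self, z, q):
        amp = ln.ScreenedBornAmplitudes()
        f = amp(z, q)
        assert f > 0
        assert amp(z, q + 0.1) < f

    def test_tabulated_provider(self):
        qs = np.linspace(0, 10, 101)
        ref = ln.ScreenedBornAmplitudes()
        tab = ln.TabulatedAmplitudes({6: (qs, ref(6, qs))})
        assert tab(6, 3.14) == pytest.approx(ref(6, 3.14), rel=1e-3)
        with pytest.raises(ValueError):
            tab(8, 1.0)


class TestIAMDCS:
    def test_single_atom_no_interference(self, amplitudes):
        s = ln.MolecularStructure.from_arrays(["C"], [[0, 0, 0]])
        tot, atom, coh = ln.iam_dcs(s, amplitudes, 100.0, 90.0)
        q = ln.momentum_transfer(100.0, 90.0)
        assert coh == 0
        assert tot == pytest.approx(amplitudes(6, q) ** 2, rel=1e-12)

    def test_homonuclear_full_coherence_limit(self, amplitudes):
        # qR -> 0: sinc -> 1 and sigma_tot -> (2 f)^2 for two equal atoms
        s = ln.MolecularStructure.from_arrays(["H", "H"], [[0, 0, 0], [0, 0, 1e-7]])
        tot, atom, coh = ln.iam_dcs(s, amplitudes, 100.0, 1e-6)
        f = amplitudes(1, ln.momentum_transfer(100.0, 1e-6))
        assert tot == pytest.approx(4 * f * f, rel=1e-9)

    def test_h2_closed_form(self, amplitudes):
        s = ln.MolecularStructure.from_arrays(["H", "H"], [[0, 0, 0], [0, 0, 1.0]])
        tot, atom, coh = ln.iam_dcs(s, amplitudes, 100.0, 180.0)
        q = ln.momentum_transfer(100.0, 180.0)
        x = q * 1.0 * BOHR_PER_ANGSTROM                      # ~10.2463
        f = amplitudes(1, q)
        assert x == pytest.approx(10.246334, abs=1e-5)
        assert tot == pytest.approx(2 * f * f * (1 + np.sin(x) / x), rel=1e-12)
        assert tot == pytest.approx(0.0078943107, abs=1e-9)

    def test_decomposition_sums(self, rng, amplitudes):
        s = random_structure(rng, 5)
        tot, atom, coh = ln.iam_dcs(s, amplitudes, 150.0, 120.0)
        assert tot == pytest.approx(atom + coh, rel=1e-14)
        assert atom > 0


def brute_force_map(structure, model, grid):
    """Element-wise pairwise-summation oracle, pure Python loops."""
    out = np.zeros(grid.shape)
    zs = structure.atomic_numbers
    xyz = structure.coords
    for a, e in enumerate(grid.return_energies):
        for b, th in enumerate(grid.rescattering_angles):
            q = ln.momentum_transfer(e, th)
            f = [model(int(z), q) for z in zs]
            total = 0.0
            for i in range(len(zs)):
                for j in range(len(zs)):
                    if i == j:
                        total += f[i] * f[i]
                    else:
                        r = np.linalg.norm(xyz[i] - xyz[j]) * BOHR_PER_ANGSTROM
                        x = q * r
                        total += f[i] * f[j] * (np.sin(x) / x if x != 0 else 1.0)
            out[a, b] = total
    return out


class TestDCSMap:
    def test_matches_brute_force_oracle(self, rng, amplitudes, small_grid):
        for n_atoms in (1, 2, 4, 6):
            s = random_structure(rng, n_atoms)
            m = ln.dcs_map(s, amplitudes, small_grid)
            assert np.allclose(m.values, brute_force_map(s, amplitudes, small_grid),
                               rtol=1e-12, atol=0)

    def test_stack_matches_single_maps(self, rng, amplitudes, small_grid):
        structures = [random_structure(rng, 4) for _ in range(3)]
        # force identical element sequences
        els = structures[0].elements
        structures = [ln.MolecularStructure.from_arrays(els, s.coords)
                      for s in structures]
        stack = ln.dcs_map_stack(structures, amplitudes, small_grid)
        for k, s in enumerate(structures):
            assert np.allclose(stack[k], ln.dcs_map(s, amplitudes, small_grid).values,
                               rtol=1e-12)

    def test_rotation_translation_invariance(self, rng, amplitudes, small_grid):
        s = random_structure(rng, 5)
        m0 = ln.dcs_map(s, amplitudes, small_grid).values
        for _ in range(4):
            s2 = s.with_coords(s.coords @ random_rotation(rng).T + rng.uniform(-3, 3, 3))
            m2 = ln.dcs_map(s2, amplitudes, small_grid).values
            assert np.allclose(m2, m0, rtol=1e-12)

    def test_nonnegative_on_default_grid(self, rng, amplitudes):
        grid = ln.default_grid(16, 16)
        for s in (ln.acetylene(), ln.carbon_disulfide(), ln.fenchone_like(),
                  random_structure(rng, 6)):
            assert ln.dcs_map(s, amplitudes, grid).values.min() >= 0

    def test_coherent_over_atomic_bounded(self, amplitudes):
        # |sigma_coh|/sigma_atom < 1 for equilibrium molecules on default grid
        grid = ln.default_grid(16, 16)
        for s in (ln.acetylene(), ln.carbon_disulfide()):
            m = ln.dcs_map(s, amplitudes, grid, store_components=True)
            ratio = np.abs(m.sigma_coherent) / m.sigma_atom
            assert ratio.max() < 1.0

    def test_diatomic_coherent_zero_crossings_at_sinc_roots(self, amplitudes):
        # sigma_coherent of a homonuclear diatomic vanishes where q R = m pi
        R = 1.2
        s = ln.MolecularStructure.from_arrays(["C", "C"], [[0, 0, 0], [0, 0, R]])
        r_bohr = R * BOHR_PER_ANGSTROM
        for m_root in (1, 2, 3):
            q_target = m_root * np.pi / r_bohr
            # invert q(E, 180 deg) for the energy giving this q
            e = (q_target / 2) ** 2 * HARTREE_EV / 2
            _, _, coh = ln.iam_dcs(s, amplitudes, e, 180.0)
            assert abs(coh) < 1e-12

    def test_coherent_envelope_decays(self, amplitudes):
        # 1/(qR) envelope: |sigma_coh|/sigma_atom at fixed angle shrinks with energy
        s = ln.MolecularStructure.from_arrays(["C", "C"], [[0, 0, 0], [0, 0, 1.2]])
        es = np.array([50.0, 200.0, 800.0, 3200.0])
        _, atom, coh = ln.iam_dcs(s, amplitudes, es, 180.0)
        envelope = 1.0 / (ln.momentum_transfer(es, 180.0) * 1.2 * BOHR_PER_ANGSTROM)
        assert np.all(np.abs(coh) / atom <= envelope * 2 + 1e-12)
        assert np.all(np.diff(envelope) < 0)

    def test_hdf5_round_trip(self, tmp_path, amplitudes, small_grid):
        m = ln.dcs_map(ln.acetylene(), amplitudes, small_grid, store_components=True)
        p = tmp_path / "map.h5"
        save_map(m, p)
        m2 = load_map(p)
        assert np.array_equal(m2.values, m.values)
        assert np.array_equal(m2.sigma_atom, m.sigma_atom)
        assert m2.grid == m.grid

    def test_csv_export_parses_back(self, tmp_path, amplitudes, small_grid):
        m = ln.dcs_map(ln.acetylene(), amplitudes, small_grid)
        p = tmp_path / "map.csv"
        export_csv(m, p)
        data = np.loadtxt(p, delimiter=",", skiprows=1)[:, 1:]
        assert np.allclose(data, m.values, rtol=1e-9)


class TestGridValidation:
    def test_bad_axes_rejected(self):
        with pytest.raises(ValueError):
            ln.DCSGrid(np.array([-1.0, 2.0]), np.array([30.0, 60.0]))
        with pytest.raises(ValueError):
            ln.DCSGrid(np.array([50.0, 100.0]), np.array([0.0, 60.0]))
        with pytest.raises(ValueError):
            ln.DCSGrid(np.array([100.0, 50.0]), np.array([30.0, 60.0]))
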