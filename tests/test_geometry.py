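"""Structures, label schemes, deformation databases and XYZ round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import liednet as ln
from liednet.geometry import (
    BentTriatomicScheme,
    CartesianSubsetScheme,
    SymmetricLinearScheme,
)

from conftest import random_rotation, random_structure


class TestStructureBasics:
    def test_atom_rejects_unknown_element(self):
        with pytest.raises(ValueError):
            ln.Atom("Xx", np.zeros(3))

    def test_atomic_numbers_match_periodic_table(self):
        s = ln.MolecularStructure.from_arrays(
            ["H", "C", "O", "S"], np.zeros((4, 3)))
        assert list(s.atomic_numbers) == [1, 6, 8, 16]

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            ln.MolecularStructure([])

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            ln.Atom("C", np.array([0.0, np.nan, 0.0]))


class TestInternuclearDistances:
    def test_two_atoms(self):
        s = ln.MolecularStructure.from_arrays(["H", "H"], [[0, 0, 0], [0, 0, 1.0]])
        assert ln.internuclear_distances(s) == pytest.approx([1.0])

    def test_single_atom_empty(self):
        s = ln.MolecularStructure.from_arrays(["C"], [[0, 0, 0]])
        assert ln.internuclear_distances(s).size == 0

    def test_equilibrium_acetylene_distances(self):
        # collinear H-C#C-H: segments 1.06 + 1.20 + 1.06
        d = sorted(ln.internuclear_distances(ln.acetylene()))
        assert d == pytest.approx([1.06, 1.06, 1.20, 2.26, 2.26, 3.32])

    @pytest.mark.parametrize("n_atoms", [2, 3, 5, 8])
    def test_pair_count(self, rng, n_atoms):
        s = random_structure(rng, n_atoms)
        assert ln.internuclear_distances(s).size == n_atoms * (n_atoms - 1) // 2

    def test_rigid_motion_invariance(self, rng):
        s = random_structure(rng, 6)
        d0 = np.sort(ln.internuclear_distances(s))
        for _ in range(5):
            rot = random_rotation(rng)
            shift = rng.uniform(-5, 5, 3)
            s2 = s.with_coords(s.coords @ rot.T + shift)
            assert np.allclose(np.sort(ln.internuclear_distances(s2)), d0,
                               rtol=0, atol=1e-9)


class TestLabelSchemes:
    def test_acetylene_equilibrium_build(self):
        s = SymmetricLinearScheme().structure([1.20, 1.06])
        xyz = s.coords
        assert np.linalg.norm(xyz[2] - xyz[1]) == pytest.approx(1.20, abs=1e-9)
        assert np.linalg.norm(xyz[1] - xyz[0]) == pytest.approx(1.06, abs=1e-9)
        assert np.linalg.norm(xyz[3] - xyz[2]) == pytest.approx(1.06, abs=1e-9)
        # collinear along z
        assert np.allclose(xyz[:, :2], 0)

    def test_cs2_collinear_ss_distance(self):
        s = BentTriatomicScheme().structure([1.55, 180.0])
        assert np.linalg.norm(s.coords[2] - s.coords[0]) == pytest.approx(3.10, abs=1e-9)

    def test_cs2_bent_ss_distance_chord_formula(self):
        s = BentTriatomicScheme().structure([1.87, 104.7])
        expected = 2 * 1.87 * np.sin(np.deg2rad(104.7) / 2)   # 2.9611707672...
        assert np.linalg.norm(s.coords[2] - s.coords[0]) == pytest.approx(expected, abs=1e-9)

    @given(r=st.floats(0.5, 3.0), theta=st.floats(10.0, 180.0))
    @settings(max_examples=50, deadline=None)
    def test_bent_triatomic_round_trip(self, r, theta):
        scheme = BentTriatomicScheme()
        out = scheme.labels(scheme.structure([r, theta]))
        assert np.allclose(out, [r, theta], rtol=0, atol=1e-9)

    @given(r1=st.floats(0.5, 3.0), r2=st.floats(0.5, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_linear_round_trip(self, r1, r2):
        scheme = SymmetricLinearScheme()
        assert np.allclose(scheme.labels(scheme.structure([r1, r2])), [r1, r2],
                           rtol=0, atol=1e-9)

    def test_cartesian_subset_round_trip(self, rng):
        base = random_structure(rng, 9)
        scheme = CartesianSubsetScheme(base, [0, 3, 7])
        v = rng.uniform(-2, 2, 9)
        assert np.allclose(scheme.labels(scheme.structure(v)), v, atol=1e-12)
        assert scheme.size == 9

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            SymmetricLinearScheme().structure([1.0, 1.0, 1.0])

    def test_nonpositive_distance_raises(self):
        with pytest.raises(ValueError):
            SymmetricLinearScheme().structure([-1.0, 1.0])
        with pytest.raises(ValueError):
            BentTriatomicScheme().structure([1.5, 200.0])


class TestGroupDeformation:
    def _spec(self, rng, n=8):
        base = random_structure(rng, n)
        return ln.DeformationSpec(mode="group-deformation", base_structure=base,
                                  groups=[[0, 1], [2, 3, 4]], count=10, seed=3)

    def test_identity(self, rng):
        spec = self._spec(rng)
        out = ln.apply_group_deformation(spec, np.zeros((2, 3)), 1.0)
        assert np.allclose(out.coords, spec.base_structure.coords)

    def test_global_scale_multiplies_all_distances(self, rng):
        spec = self._spec(rng)
        out = ln.apply_group_deformation(spec, np.zeros((2, 3)), 1.1)
        d0 = ln.internuclear_distances(spec.base_structure)
        assert np.allclose(ln.internuclear_distances(out), 1.1 * d0, rtol=1e-12)

    def test_single_group_shift_matches_direct_arithmetic(self, rng):
        spec = self._spec(rng)
        shift = np.array([[0, 0, 0.1], [0, 0, 0]])
        out = ln.apply_group_deformation(spec, shift, 1.0)
        expected = spec.base_structure.coords.copy()
        expected[[0, 1]] += [0, 0, 0.1]
        assert np.allclose(out.coords, expected, atol=1e-12)
        # intra-group distances unchanged
        d_new = np.linalg.norm(out.coords[0] - out.coords[1])
        d_old = np.linalg.norm(expected[0] - expected[1])
        assert d_new == pytest.approx(d_old, abs=1e-12)

    def test_invalid_arguments(self, rng):
        spec = self._spec(rng)
        with pytest.raises(ValueError):
            ln.apply_group_deformation(spec, np.zeros((2, 3)), 0.0)
        with pytest.raises(ValueError):
            ln.apply_group_deformation(spec, np.zeros((3, 3)), 1.0)

    def test_overlapping_groups_rejected(self, rng):
        base = random_structure(rng, 5)
        with pytest.raises(ValueError):
            ln.DeformationSpec(mode="group-deformation", base_structure=base,
                               groups=[[0, 1], [1, 2]], count=5)


class TestGenerateDatabase:
    def test_grid_cardinality(self):
        spec = ln.DeformationSpec(
            mode="parameter-grid", scheme=ln.SymmetricLinearScheme(),
            parameters=[("R_CC", 1.0, 1.4, 21), ("R_CH", 0.86, 1.26, 21)])
        db = ln.generate_database(spec)
        assert len(db) == 441

    def test_sampled_determinism_and_range(self):
        def make():
            spec = ln.DeformationSpec(
                mode="parameter-grid", scheme=ln.SymmetricLinearScheme(),
                parameters=[("R_CC", 1.0, 1.4, "uniform"),
                            ("R_CH", 0.86, 1.26, "uniform")],
                count=50, seed=5)
            return ln.generate_database(spec)
        l1 = np.array([v for _, v in make()])
        l2 = np.array([v for _, v in make()])
        assert np.array_equal(l1, l2)
        assert l1[:, 0].min() >= 1.0 and l1[:, 0].max() <= 1.4
        assert l1[:, 1].min() >= 0.86 and l1[:, 1].max() <= 1.26

    def test_group_mode_count_and_determinism(self, rng):
        base = random_structure(rng, 6)
        def make():
            spec = ln.DeformationSpec(mode="group-deformation", base_structure=base,
                                      groups=[[0, 1], [2, 3]], count=40, seed=9)
            return ln.generate_database(spec)
        db1, db2 = make(), make()
        assert len(db1) == 40
        assert np.array_equal(np.array([v for _, v in db1]),
                              np.array([v for _, v in db2]))

    def test_empty_parameters_rejected(self):
        with pytest.raises(ValueError):
            ln.DeformationSpec(mode="parameter-grid",
                               scheme=ln.SymmetricLinearScheme(), parameters=[])


class TestXYZ:
    def test_round_trip(self, rng, tmp_path):
        s = random_structure(rng, 27)
        p = tmp_path / "mol.xyz"
        ln.write_xyz(s, p)
        s2 = ln.read_xyz(p)
        assert s2.elements == s.elements
        assert np.allclose(s2.coords, s.coords, atol=1e-6)

    def test_literal_parse(self, tmp_path):
        p = tmp_path / "three.xyz"
        p.write_text("3\nwater-ish\nO 0.0 0.0 0.1\nH 0.8 0.0 -0.4\nH -0.8 0.0 -0.4\n")
        s = ln.read_xyz(p)
        assert s.elements == ["O", "H", "H"]
        assert np.allclose(s.coords[1], [0.8, 0.0, -0.4])

    def test_count_mismatch_raises(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("4\noops\nC 0 0 0\nC 0 0 1\n")
        with pytest.raises(ValueError):
            ln.read_xyz(p)

    def test_packaged_fenchone_like(self):
        s = ln.fenchone_like()
        assert len(s) == 27
        assert s.formula() == "C10H16O"
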