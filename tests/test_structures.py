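"""Structure parsing, parameter assignment, orientations, shape measures."""

import math

import numpy as np
import pytest

from crowdxfer import (ForceFieldTable, Molecule, ParameterError,
                       parallel_body_measures, random_orientation,
                       read_structure, sphere_measures, write_pdb)
from crowdxfer.structures import random_rotation

PDB_3ATOM = """\
ATOM      1  C   MOL A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   MOL A   1       1.500   0.000   0.000  1.00  0.00           N
ATOM      3  O   MOL A   1       0.000   1.500   0.000  1.00  0.00           O
END
"""

PQR_2ATOM = """\
ATOM      1  C   MOL     1       0.000   0.000   0.000  0.2500 1.9000
ATOM      2  O   MOL     1       2.000   0.000   0.000 -0.2500 1.4000
END
"""

PDB_UNKNOWN = """\
HETATM    1 XX   LIG A   1       0.000   0.000   0.000  1.00  0.00          XX
END
"""


class TestReadStructure:
    def test_pdb_atoms_typed_from_table(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(PDB_3ATOM)
        table = ForceFieldTable.bundled()
        mol = read_structure(p, table)
        assert len(mol) == 3
        assert mol.labels == ["C", "N", "O"]
        for label, r in zip(mol.labels, mol.radii):
            assert r == table.entries[label][0]
        np.testing.assert_allclose(mol.coords[1], [1.5, 0, 0])

    def test_pqr_radius_and_charge_override_table(self, tmp_path):
        p = tmp_path / "two.pqr"
        p.write_text(PQR_2ATOM)
        mol = read_structure(p)
        np.testing.assert_allclose(mol.radii, [1.9, 1.4])
        np.testing.assert_allclose(mol.charges, [0.25, -0.25])

    def test_unknown_atom_type_is_named_in_error(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(PDB_UNKNOWN)
        with pytest.raises(ParameterError, match="XX"):
            read_structure(p)

    def test_lenient_table_falls_back_to_element(self, tmp_path):
        p = tmp_path / "bad.pdb"
        # HETATM with unknown type CA -> falls back to C when lenient
        p.write_text(PDB_UNKNOWN.replace("XX   LIG", "CX   LIG")
                     .replace("          XX", "          CX"))
        mol = read_structure(p, ForceFieldTable.bundled(lenient=True))
        assert len(mol) == 1

    def test_pdb_write_read_roundtrip(self, tmp_path, toy_molecule):
        p = tmp_path / "toy.pdb"
        write_pdb(toy_molecule, p)
        back = read_structure(p, ForceFieldTable.bundled())
        np.testing.assert_allclose(back.coords, toy_molecule.coords,
                                   atol=1.5e-3)


class TestRandomOrientation:
    def test_single_atom_invariant(self, make_atom):
        m = make_atom(pos=(1.0, 2.0, 3.0))
        for seed in (0, 1, 99):
            np.testing.assert_array_equal(
                random_orientation(m, seed).coords, m.coords)

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_rigidity(self, toy_molecule, seed):
        rot = random_orientation(toy_molecule, seed)
        d0 = np.linalg.norm(toy_molecule.coords[:, None]
                            - toy_molecule.coords[None], axis=-1)
        d1 = np.linalg.norm(rot.coords[:, None] - rot.coords[None], axis=-1)
        np.testing.assert_allclose(d1, d0, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(rot.centroid, toy_molecule.centroid,
                                   atol=1e-9)

    def test_deterministic_for_fixed_seed(self, toy_molecule):
        a = random_orientation(toy_molecule, 42)
        b = random_orientation(toy_molecule, 42)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_axis_distribution_uniform_on_sphere(self):
        """The axis of the axis-angle scheme covers all octants evenly
        (the scheme itself is not Haar-uniform over rotations)."""
        rng = np.random.default_rng(3)
        axes = []
        for _ in range(10_000):
            rv = random_rotation(rng, "axis-angle").as_rotvec()
            norm = np.linalg.norm(rv)
            if norm > 1e-12:
                axes.append(rv / norm)
        axes = np.array(axes)
        octant = (axes > 0) @ np.array([4, 2, 1])
        counts = np.bincount(octant, minlength=8)
        # each octant expected n/8 = 1250; 5 sigma ~ 165
        assert np.all(np.abs(counts - len(axes) / 8) < 170)
        assert np.abs(axes.mean(axis=0)).max() < 0.03

    def test_uniform_quaternion_scheme_available(self, toy_molecule):
        rot = random_orientation(toy_molecule, 1, scheme="uniform")
        d0 = np.linalg.norm(toy_molecule.coords[0] - toy_molecule.coords[-1])
        d1 = np.linalg.norm(rot.coords[0] - rot.coords[-1])
        assert math.isclose(d0, d1, rel_tol=1e-9)


class TestShapeMeasures:
    def test_single_sphere_analytic(self, make_atom):
        sm = parallel_body_measures(make_atom(2.0), 3.0, 0.25)
        ex = sphere_measures(2.0)
        assert sm.v_p == pytest.approx(ex.v_p, rel=0.02)
        assert sm.s_p == pytest.approx(ex.s_p, rel=0.02)
        assert sm.l_p == pytest.approx(ex.l_p, rel=0.02)

    def test_fully_overlapping_pair_equals_single(self):
        one = Molecule("one", ["C"], [[0, 0, 0]], [2.0], [0.], [0.], [0.])
        two = Molecule("two", ["C"] * 2, [[0, 0, 0], [0, 0, 0]], [2.0] * 2,
                       [0.] * 2, [0.] * 2, [0.] * 2)
        a = parallel_body_measures(one, 3.0, 0.25)
        b = parallel_body_measures(two, 3.0, 0.25)
        assert a == b

    def test_disjoint_pair_additive(self):
        two = Molecule("two", ["C"] * 2, [[0, 0, 0], [30, 0, 0]], [2.0] * 2,
                       [0.] * 2, [0.] * 2, [0.] * 2)
        sm = parallel_body_measures(two, 3.0, 0.25)
        ex = sphere_measures(2.0)
        assert sm.v_p == pytest.approx(2 * ex.v_p, rel=0.02)
        assert sm.s_p == pytest.approx(2 * ex.s_p, rel=0.02)
        assert sm.l_p == pytest.approx(2 * ex.l_p, rel=0.02)

    @pytest.mark.parametrize("spacing", [0.4, 0.2])
    def test_rotation_invariance_within_grid_tolerance(self, toy_molecule,
                                                       spacing):
        rot = random_orientation(toy_molecule, 17)
        a = parallel_body_measures(toy_molecule, 4.0, spacing)
        b = parallel_body_measures(rot, 4.0, spacing)
        assert b.v_p == pytest.approx(a.v_p, rel=0.02)
        assert b.s_p == pytest.approx(a.s_p, rel=0.05)
        assert b.l_p == pytest.approx(a.l_p, rel=0.05)

    def test_spacing_refinement_converges_to_analytic(self, make_atom):
        ex = sphere_measures(2.0)
        errs = []
        for h in (0.5, 0.25, 0.125):
            sm = parallel_body_measures(make_atom(2.0), 3.0, h)
            errs.append(abs(sm.v_p - ex.v_p) + abs(sm.s_p - ex.s_p)
                        + abs(sm.l_p - ex.l_p))
        assert errs[2] < errs[0]

    def test_all_measures_nonnegative(self, toy_molecule):
        sm = parallel_body_measures(toy_molecule, 5.0, 0.3)
        assert sm.v_p >= 0 and sm.s_p >= 0 and sm.l_p >= 0
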