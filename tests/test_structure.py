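"""Superposition, rotation extraction and conformational metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from bphpkit.simulate import (
    GeneratorSpec,
    NoiseModel,
    _rotation_matrix,
    make_ideal_helix,
    make_rotated_pair,
)
from bphpkit.structure import (
    Selection,
    StructureModel,
    domain_rotation,
    helix_scissor_angle,
    pair_distance,
    plane_flip_angle,
    read_structure,
    rotation_angle,
    superpose,
    write_pdb,
)

MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.000   4.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       1.000   1.000   2.000  1.00  0.00           C
END
"""

MINIMAL_CIF = """\
data_fix
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.auth_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_asym_id
_atom_site.pdbx_PDB_model_num
ATOM 1 C CA . ALA A 1 1 1 0.000 0.000 0.000 1.00 0.00 A 1
ATOM 2 C CA . ALA A 1 2 2 3.000 4.000 0.000 1.00 0.00 A 1
ATOM 3 C CA . ALA A 1 3 3 1.000 1.000 2.000 1.00 0.00 A 1
"""


@pytest.fixture
def rotated_pair():
    return make_rotated_pair(GeneratorSpec(seed=1), angle_deg=35.0,
                             with_ring=True, ring_flip_deg=90.0)


class TestReadStructure:
    def test_minimal_pdb(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        model = read_structure(p)
        assert len(model) == 3
        assert model.chains == {"A"}

    def test_pdb_mmcif_equivalence(self, tmp_path):
        p1 = tmp_path / "mini.pdb"
        p1.write_text(MINIMAL_PDB)
        p2 = tmp_path / "mini.cif"
        p2.write_text(MINIMAL_CIF)
        a = read_structure(p1, format="pdb")
        b = read_structure(p2, format="mmcif")
        np.testing.assert_allclose(a.coords(), b.coords())

    def test_unparseable_file_signalled(self, tmp_path):
        p = tmp_path / "junk.pdb"
        p.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            read_structure(p)

    def test_write_read_round_trip(self, tmp_path, rotated_pair):
        a, _, _ = rotated_pair
        path = tmp_path / "a.pdb"
        write_pdb(a, path)
        back = read_structure(path)
        assert len(back) == len(a)
        # PDB format carries 3 decimals
        assert np.max(np.abs(back.coords() - a.coords())) < 1e-3


class TestSuperpose:
    def test_identity_on_identical_sets(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3))
        res = superpose(X, X)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)

    def test_recovers_known_30_degree_rotation(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(10, 3))
        R = _rotation_matrix(np.array([0.0, 0.0, 1.0]), 30.0)
        Q = P @ R.T + np.array([1.0, 2.0, 3.0])
        res = superpose(P, Q)
        angle, axis = rotation_angle(res.rotation)
        assert angle == pytest.approx(30.0, abs=1e-6)
        assert res.rmsd < 1e-8
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-8)

    def test_agrees_with_scipy_align_vectors(self):
        # independent oracle for the optimal rotation
        rng = np.random.default_rng(2)
        P = rng.normal(size=(12, 3))
        Q = rng.normal(size=(12, 3))
        res = superpose(P, Q)
        rot, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        np.testing.assert_allclose(res.rotation, rot.as_matrix(), atol=1e-9)

    def test_mirror_image_returns_proper_rotation(self):
        rng = np.random.default_rng(3)
        P = rng.normal(size=(10, 3))
        Q = P * np.array([-1.0, 1.0, 1.0])
        res = superpose(P, Q)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-10)
        assert res.rmsd > 0.1

    def test_brute_force_never_beats_kabsch(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        best = superpose(P, Q).rmsd
        P0 = P - P.mean(0)
        Q0 = Q - Q.mean(0)
        random_rots = Rotation.random(1000, random_state=5)
        for R in random_rots.as_matrix():
            rmsd = np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1)))
            assert rmsd >= best - 1e-12

    def test_degenerate_geometry_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            superpose(line, line)
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRotationAngle:
    def test_identity(self):
        angle, _ = rotation_angle(np.eye(3))
        assert angle == pytest.approx(0.0)

    def test_half_turn_about_z(self):
        angle, axis = rotation_angle(np.diag([-1.0, -1.0, 1.0]))
        assert angle == pytest.approx(180.0)
        np.testing.assert_allclose(axis, [0, 0, 1], atol=1e-10)

    def test_composition_matches_quaternion_oracle(self):
        axis = np.array([1.0, 2.0, 0.5])
        axis /= np.linalg.norm(axis)
        R = _rotation_matrix(axis, 20.0) @ _rotation_matrix(axis, 25.0)
        angle, _ = rotation_angle(R)
        oracle = Rotation.from_matrix(R).magnitude()
        assert angle == pytest.approx(45.0, abs=1e-9)
        assert angle == pytest.approx(np.degrees(oracle), abs=1e-9)

    def test_non_orthogonal_rejected(self):
        with pytest.raises(ValueError):
            rotation_angle(np.eye(3) + 1e-3)


class TestDomainRotation:
    ALIGN = Selection(chain="A", residue_range=(1, 30))
    MEASURE = Selection(chain="A", residue_range=(101, 130))

    def test_identical_states_give_zero(self, rotated_pair):
        a, _, _ = rotated_pair
        assert domain_rotation(a, a, self.ALIGN, self.MEASURE) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_35_degrees(self, rotated_pair):
        a, b, truth = rotated_pair
        angle = domain_rotation(a, b, self.ALIGN, self.MEASURE)
        assert angle == pytest.approx(truth.angle_deg, abs=0.1)

    def test_frame_invariance(self, rotated_pair):
        a, b, truth = rotated_pair
        R = _rotation_matrix(np.array([0.2, 0.9, 0.4]), 73.0)
        t = np.array([10.0, -4.0, 6.0])
        a2 = a.transformed(R, t)
        b2 = b.transformed(R, t)
        ref = domain_rotation(a, b, self.ALIGN, self.MEASURE)
        moved = domain_rotation(a2, b2, self.ALIGN, self.MEASURE)
        assert moved == pytest.approx(ref, abs=1e-6)

    def test_empty_selection_signalled(self, rotated_pair):
        a, b, _ = rotated_pair
        with pytest.raises(ValueError):
            domain_rotation(a, b, self.ALIGN,
                            Selection(chain="Z", residue_range=(1, 5)))


class TestPlaneFlip:
    RING = Selection(chain="A", residue_range=None, ligand="RNG",
                     atom_names=("ND", "C1D", "C2D", "C3D", "C4D"))
    ALIGN = Selection(chain="A", residue_range=(1, 30))

    def test_identical_states_zero(self, rotated_pair):
        a, _, _ = rotated_pair
        assert plane_flip_angle(a, a, self.RING, self.ALIGN) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_90_degree_flip(self, rotated_pair):
        a, b, _ = rotated_pair
        angle = plane_flip_angle(a, b, self.RING, self.ALIGN)
        assert angle == pytest.approx(90.0, abs=1e-6)

    def test_oriented_flip_exceeds_90(self):
        a, b, _ = make_rotated_pair(GeneratorSpec(seed=1), angle_deg=35.0,
                                    with_ring=True, ring_flip_deg=161.0)
        angle = plane_flip_angle(a, b, self.RING, self.ALIGN)
        assert angle == pytest.approx(161.0, abs=1e-6)


class TestPairDistance:
    def test_atom_with_itself(self, rotated_pair):
        a, _, _ = rotated_pair
        assert pair_distance(a, ("A", 1, "CA"), ("A", 1, "CA")) == 0.0

    def test_three_four_five(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        model = read_structure(p)
        assert pair_distance(model, ("A", 1, "CA"), ("A", 2, "CA")) == pytest.approx(5.0)

    def test_missing_atom_named_in_error(self, rotated_pair):
        a, _, _ = rotated_pair
        with pytest.raises(KeyError, match="999/CB"):
            pair_distance(a, ("A", 1, "CA"), ("A", 999, "CB"))


class TestHelixScissor:
    @staticmethod
    def _two_helix_state(cross_deg: float) -> StructureModel:
        # 18 residues at 100 deg/residue is exactly five full turns, so the
        # CA centroid sits on the helix axis and the PCA axis is exact
        h1 = make_ideal_helix(18, chain="A", start_res=1, direction=(0, 0, 1))
        rad = np.radians(cross_deg)
        h2 = make_ideal_helix(18, chain="B", start_res=1, origin=(10, 0, 0),
                              direction=(np.sin(rad), 0.0, np.cos(rad)))
        return StructureModel(id="helices",
                              atoms=pd.concat([h1, h2], ignore_index=True))

    @pytest.mark.parametrize("cross,expected,tol", [
        (0.0, 0.0, 0.5), (40.0, 40.0, 1.0), (90.0, 90.0, 1.0)])
    def test_crossing_angles(self, cross, expected, tol):
        state = self._two_helix_state(cross)
        angle = helix_scissor_angle(state,
                                    Selection(chain="A", residue_range=(1, 18)),
                                    Selection(chain="B", residue_range=(1, 18)))
        assert angle == pytest.approx(expected, abs=tol)

    def test_too_few_residues_rejected(self):
        state = self._two_helix_state(30.0)
        with pytest.raises(ValueError):
            helix_scissor_angle(state,
                                Selection(chain="A", residue_range=(1, 3)),
                                Selection(chain="B", residue_range=(1, 18)))


class TestSelectionParsing:
    def test_cli_syntax(self):
        sel = Selection.parse("A:120-320:CA")
        assert sel.chain == "A"
        assert sel.residue_range == (120, 320)
        assert sel.atom_names == ("CA",)

    def test_invalid_syntax_rejected(self):
        with pytest.raises(ValueError):
            Selection.parse("A")
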