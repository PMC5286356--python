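import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from softcontact import (
    StructureModel,
    closest_symmetry_contact,
    kabsch_superpose,
    min_atom_distance,
    min_interchain_ca_distance,
    polar_contact_inventory,
    symmetry_expand,
)
from softcontact.structure_io import AtomRecord, CrystalCell, SymOp


def _atom(serial, xyz, name="CA", element="C", chain="A", resseq=1, resname="ALA"):
    return AtomRecord(
        serial=serial, name=name, element=element, altloc="", resname=resname,
        chain=chain, resseq=resseq, icode="", xyz=tuple(map(float, xyz)),
        occupancy=1.0, bfactor=10.0, is_water=False, is_hetero=False,
    )


def _cloud(rng, n, chain, base_serial, spread=20.0):
    pts = rng.uniform(-spread, spread, (n, 3))
    return [
        _atom(base_serial + i, p, chain=chain, resseq=i + 1) for i, p in enumerate(pts)
    ]


class TestMinDistance:
    def test_two_atoms_five_angstrom(self):
        a = [_atom(1, (0, 0, 0))]
        b = [_atom(2, (5, 0, 0), chain="B")]
        d, pair = min_atom_distance(a, b)
        assert d == pytest.approx(5.0)
        assert pair[0].serial == 1 and pair[1].serial == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        a = _cloud(rng, 50, "A", 1)
        b = _cloud(rng, 50, "B", 100)
        d, _ = min_atom_distance(a, b)
        brute = min(
            np.linalg.norm(np.subtract(x.xyz, y.xyz)) for x in a for y in b
        )
        assert d == pytest.approx(brute, abs=1e-12)

    def test_tie_broken_by_lowest_serials(self):
        a = [_atom(3, (0, 0, 0)), _atom(1, (0, 0, 2))]
        b = [_atom(9, (1, 0, 0), chain="B"), _atom(7, (1, 0, 2), chain="B", resseq=2)]
        _, pair = min_atom_distance(a, b)
        assert (pair[0].serial, pair[1].serial) == (1, 7)

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError):
            min_atom_distance([], [_atom(1, (0, 0, 0))])


class TestMinCaDistance:
    def test_single_residue_pair(self):
        a = [_atom(1, (0, 0, 0), name="CA")]
        b = [_atom(2, (7, 0, 0), name="CA", chain="B")]
        d, pair = min_interchain_ca_distance(a, b)
        assert d == pytest.approx(7.0)
        assert pair == (("A", 1, ""), ("B", 1, ""))

    def test_non_ca_atoms_ignored(self):
        a = [_atom(1, (0, 0, 0), name="CA"), _atom(2, (1, 0, 0), name="CB")]
        b = [_atom(3, (6, 0, 0), name="CB", chain="B"), _atom(4, (8, 0, 0), name="CA", chain="B")]
        d, _ = min_interchain_ca_distance(a, b)
        assert d == pytest.approx(8.0)

    def test_calcium_is_not_c_alpha(self):
        a = [_atom(1, (0, 0, 0), name="CA")]
        b = [_atom(2, (3, 0, 0), name="CA", element="CA", resname="CA", chain="B")]
        with pytest.raises(ValueError, match="C"):
            min_interchain_ca_distance(a, b)


class TestPolarContacts:
    def test_salt_bridge_labeling(self):
        nz = _atom(1, (0, 0, 0), name="NZ", element="N", resname="LYS")
        od2 = _atom(2, (2.7, 0, 0), name="OD2", element="O", resname="ASP", chain="B")
        recs = polar_contact_inventory([nz], [od2])
        assert len(recs) == 1
        assert recs[0].kind == "salt_bridge"
        assert recs[0].distance == pytest.approx(2.7)

    def test_plain_polar_pair_is_hydrogen_bond(self):
        n = _atom(1, (0, 0, 0), name="N", element="N")
        o = _atom(2, (3.0, 0, 0), name="O", element="O", chain="B")
        recs = polar_contact_inventory([n], [o])
        assert recs[0].kind == "hydrogen_bond"

    def test_cutoff_and_sorting(self):
        a = [
            _atom(1, (0, 0, 0), name="N", element="N"),
            _atom(2, (0, 5, 0), name="O", element="O", resseq=2),
        ]
        b = [
            _atom(3, (3.4, 0, 0), name="O", element="O", chain="B"),
            _atom(4, (0, 5, 2.5), name="N", element="N", chain="B", resseq=2),
            _atom(5, (0, 0, 9), name="O", element="O", chain="B", resseq=3),
        ]
        recs = polar_contact_inventory(a, b)
        assert [r.distance for r in recs] == sorted(r.distance for r in recs)
        assert len(recs) == 2  # the 9 Å pair is out

    def test_carbon_atoms_never_counted(self):
        a = [_atom(1, (0, 0, 0), name="CB", element="C")]
        b = [_atom(2, (3.0, 0, 0), name="CB", element="C", chain="B")]
        assert polar_contact_inventory(a, b) == []


class TestKabsch:
    def test_identity_rmsd_zero(self):
        rng = np.random.default_rng(0)
        P = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, np.eye(3), atol=1e-8)

    @pytest.mark.parametrize("seed", range(8))
    def test_planted_rigid_motion_recovered(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(25, 3)) * 10
        rot = Rotation.random(random_state=seed).as_matrix()
        shift = rng.normal(size=3) * 5
        Q = P @ rot.T + shift
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(P @ R.T + t, Q, atol=1e-8)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_scipy_on_noisy_sets(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(30, 3)) * 8
        rot = Rotation.random(random_state=100 + seed).as_matrix()
        Q = P @ rot.T + rng.normal(size=3) + rng.normal(scale=0.3, size=P.shape)
        _, _, rmsd = kabsch_superpose(P, Q)
        ref_rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert rmsd == pytest.approx(rssd / np.sqrt(len(P)), rel=1e-6)

    def test_reflection_never_returned(self):
        # a near-planar set invites an improper solution; det must stay +1
        rng = np.random.default_rng(5)
        P = rng.normal(size=(12, 3))
        P[:, 2] *= 1e-4
        Q = P.copy()
        Q[:, 0] *= -1  # mirrored target
        R, _, _ = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_input_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_superpose(P, P + 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


def _p1_model(atoms, edge=10.0):
    ident = SymOp(rot=tuple(map(tuple, np.eye(3))), tran=(0.0, 0.0, 0.0), triplet="x,y,z")
    cell = CrystalCell(edge, edge, edge, 90, 90, 90, "P 1", (ident,))
    return StructureModel(atoms=atoms, cell=cell)


class TestSymmetry:
    def test_p1_single_atom_26_translation_images(self):
        model = _p1_model([_atom(1, (5, 5, 5))])
        images = symmetry_expand(model, shell=100.0)
        assert len(images) == 26

    def test_p21_image_matches_hand_transform(self):
        # orthogonal P2_1 cell so the fractional math is a hand calculation:
        # (x,y,z) -> (-x, y+1/2, -z); frac (0.1,0.2,0.3) in a 10x20x30 cell
        ident = SymOp(rot=tuple(map(tuple, np.eye(3))), tran=(0, 0, 0), triplet="x,y,z")
        screw = SymOp(
            rot=((-1.0, 0, 0), (0, 1.0, 0), (0, 0, -1.0)), tran=(0.0, 0.5, 0.0),
            triplet="-x,y+1/2,-z",
        )
        cell = CrystalCell(10, 20, 30, 90, 90, 90, "P 1 21 1", (ident, screw))
        model = StructureModel(atoms=[_atom(1, (1.0, 4.0, 9.0))], cell=cell)
        images = symmetry_expand(model, shell=100.0)
        screw_zero = [
            i for i in images if i.op_triplet == "-x,y+1/2,-z" and i.shift == (0, 0, 0)
        ]
        assert len(screw_zero) == 1
        np.testing.assert_allclose(screw_zero[0].coords[0], [-1.0, 14.0, -9.0], atol=1e-9)

    def test_images_are_isometric(self, toy_roundtrip):
        model, _, _ = toy_roundtrip
        sub = model.atoms[:15]
        submodel = StructureModel(atoms=sub, cell=model.cell)
        ref = np.array([a.xyz for a in sub])
        ref_d = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
        for img in symmetry_expand(submodel, shell=200.0)[:6]:
            d = np.linalg.norm(img.coords[:, None] - img.coords[None, :], axis=-1)
            np.testing.assert_allclose(d, ref_d, atol=1e-6)

    def test_closest_contact_p1_cubic_cell(self):
        model = _p1_model([_atom(1, (5, 5, 5))], edge=10.0)
        assert closest_symmetry_contact(model, model.atoms) == pytest.approx(10.0)

    def test_closest_contact_equals_brute_force(self, toy_roundtrip):
        model, _, _ = toy_roundtrip
        sub = StructureModel(atoms=model.atoms[:40], cell=model.cell)
        got = closest_symmetry_contact(sub, sub.atoms)
        cell = sub.cell
        orth, frac = cell.orth, cell.frac
        xyz = np.array([a.xyz for a in sub.atoms])
        fx = xyz @ frac.T
        best = np.inf
        for op in cell.symops:
            rot, tran = np.asarray(op.rot), np.asarray(op.tran)
            for shift in itertools.product((-1, 0, 1), repeat=3):
                if op.is_identity and shift == (0, 0, 0):
                    continue
                img = (fx @ rot.T + tran + np.array(shift)) @ orth.T
                d = np.linalg.norm(xyz[:, None] - img[None, :], axis=-1).min()
                best = min(best, d)
        assert got == pytest.approx(best, abs=1e-9)

    def test_no_cell_errors(self):
        model = StructureModel(atoms=[_atom(1, (0, 0, 0))])
        with pytest.raises(Exception, match="cell"):
            closest_symmetry_contact(model, model.atoms)
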