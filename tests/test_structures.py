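"""Structure I/O, generic numbering, pocket panels, RMSD and superposition."""

import itertools
import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from siftkit.datasets import generic_mapping_path
from siftkit.structures import (
    Complex,
    LigandPose,
    ReceptorStructure,
    load_complex,
    load_ligand,
    load_receptor,
    load_trajectory,
    map_generic_numbers,
    pocket_panel,
    pose_rmsd,
    read_generic_mapping,
    superpose_frames,
    write_complex,
    write_trajectory,
)
from siftkit.synthetic_data import SyntheticSpec, make_residue, simulate_complex, simulate_trajectory

# binding-site generic positions recurring in 5-HT5A contact analyses
LITERATURE_PANEL = [
    "2x64", "3x28", "3x29", "3x32", "3x33", "3x36", "45x50", "45x51", "45x52",
    "45x53", "5x36", "5x39", "5x40", "5x43", "5x44", "4x56", "4x57", "4x60",
    "4x61", "6x48", "6x51", "6x52", "6x55", "7x38", "7x42",
]


def _toy_receptor():
    return ReceptorStructure([make_residue("SER", "A", 10),
                              make_residue("GLY", "A", 11, origin=(6, 0, 0)),
                              make_residue("ALA", "A", 12, origin=(-6, 0, 0))])


def _toy_ligand(offset=(0.0, 0.0, 3.0)):
    coords = np.array([[0, 0, 0], [1.4, 0, 0], [2.1, 1.2, 0], [3.5, 1.2, 0],
                       [4.2, 2.4, 0.0]], dtype=float) + np.asarray(offset)
    return LigandPose(["C", "C", "O", "C", "N"], coords, [0] * 5,
                      [(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 4, 1)])


class TestIO:
    def test_pdb_sdf_complex_loads(self, tmp_path):
        cx = Complex(_toy_receptor(), _toy_ligand())
        write_complex(cx, tmp_path / "rec.pdb")
        mol = cx.ligand.to_rdkit()
        with Chem.SDWriter(str(tmp_path / "lig.sdf")) as w:
            w.write(mol)
        loaded = load_complex(tmp_path / "rec.pdb", tmp_path / "lig.sdf")
        assert len(loaded.receptor.residues) == 3
        assert len(loaded.ligand.elements) == 5
        np.testing.assert_allclose(loaded.ligand.coords, cx.ligand.coords, atol=1e-2)

    def test_hetatm_route_equals_split_route(self, tmp_path):
        cx = Complex(_toy_receptor(), _toy_ligand())
        write_complex(cx, tmp_path / "both.pdb")
        mol = cx.ligand.to_rdkit()
        with Chem.SDWriter(str(tmp_path / "lig.sdf")) as w:
            w.write(mol)
        split = load_complex(tmp_path / "both.pdb", tmp_path / "lig.sdf")
        embedded = load_complex(tmp_path / "both.pdb", None, ligand_residue="LIG")
        assert embedded.ligand.elements == split.ligand.elements
        np.testing.assert_allclose(embedded.ligand.coords, split.ligand.coords,
                                   atol=1e-2)
        assert [r.key for r in embedded.receptor.residues] == \
               [r.key for r in split.receptor.residues]

    def test_sdf_charge_block_populates_formal_charges(self, tmp_path):
        mol = Chem.AddHs(Chem.MolFromSmiles("CC(=O)[O-]"))
        AllChem.EmbedMolecule(mol, randomSeed=7)
        mol = Chem.RemoveHs(mol)
        with Chem.SDWriter(str(tmp_path / "acetate.sdf")) as w:
            w.write(mol)
        pose = load_ligand(tmp_path / "acetate.sdf")
        assert sum(pose.formal_charges) == -1

    def test_missing_ligand_selection_raises(self, tmp_path):
        cx = Complex(_toy_receptor(), _toy_ligand())
        write_complex(cx, tmp_path / "rec.pdb")
        with pytest.raises(ValueError):
            load_ligand(tmp_path / "rec.pdb", format="pdb", residue_name="XYZ")

    def test_trajectory_roundtrip(self, tmp_path):
        base, _ = simulate_complex("ionic", seed=3)
        frames, _ = simulate_trajectory(base, SyntheticSpec(seed=3), n_frames=4)
        write_trajectory(frames, tmp_path / "traj.pdb")
        back = load_trajectory(tmp_path / "traj.pdb")
        assert len(back) == 4
        for orig, loaded in zip(frames, back):
            np.testing.assert_allclose(loaded.ligand.coords, orig.ligand.coords,
                                       atol=1e-2)


class TestGenericNumbers:
    def test_mapping_annotates_matching_residue(self):
        receptor = _toy_receptor()
        _, unmatched = map_generic_numbers(receptor, {("A", 10): "3x32"})
        assert receptor.residue("A", 10).generic_number == "3x32"
        assert unmatched == []

    def test_empty_mapping_is_a_noop(self):
        receptor = _toy_receptor()
        _, unmatched = map_generic_numbers(receptor, {})
        assert all(r.generic_number is None for r in receptor.residues)
        assert unmatched == []

    def test_duplicate_generic_labels_rejected(self):
        with pytest.raises(ValueError):
            map_generic_numbers(_toy_receptor(), {("A", 10): "3x32",
                                                  ("A", 11): "3x32"})

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            map_generic_numbers(_toy_receptor(), {("A", 10): "helix3-32"})

    def test_bundled_mapping_covers_reported_panel(self):
        """The shipped (synthetic-numbering) 5-HT5A mapping covers all 25
        binding-site generic positions the contact analyses refer to."""
        mapping = read_generic_mapping(generic_mapping_path())
        labels = set(mapping.values())
        assert set(LITERATURE_PANEL) <= labels
        receptor = ReceptorStructure(
            [make_residue("GLY", chain, num, origin=(i * 4.0, 0, 0))
             for i, (chain, num) in enumerate(sorted(mapping))])
        receptor, unmatched = map_generic_numbers(receptor, mapping)
        assert unmatched == []
        annotated = {r.generic_number for r in receptor.residues} - {None}
        assert len(annotated & set(LITERATURE_PANEL)) == 25


class TestPocketPanel:
    def test_only_nearby_residue_selected(self):
        cx = Complex(_toy_receptor(), _toy_ligand(offset=(0.55, -2.0, 2.0)))
        rec = cx.receptor
        # place other residues far away
        far = ReceptorStructure([rec.residues[0],
                                 make_residue("GLY", "A", 11, origin=(25, 0, 0)),
                                 make_residue("ALA", "A", 12, origin=(-25, 0, 0))])
        panel = pocket_panel(Complex(far, cx.ligand), cutoff_A=6.0)
        assert [r.key for r in panel] == [("A", 10, "")]

    def test_zero_cutoff_empty(self, ionic_complex):
        cx, _ = ionic_complex
        assert pocket_panel(cx, cutoff_A=0.0) == []

    def test_monotone_in_cutoff(self, ionic_complex):
        cx, _ = ionic_complex
        keys = [set(r.key for r in pocket_panel(cx, c)) for c in (3, 5, 8, 15)]
        for smaller, larger in zip(keys, keys[1:]):
            assert smaller <= larger

    def test_matches_brute_force_scan(self):
        """k-d-tree panel equals the O(N^2) all-pairs distance scan."""
        archetypes = ("hbond", "ionic", "aromatic", "hydrophobic", "no_contact")
        for seed in range(20):
            cx, _ = simulate_complex(archetypes[seed % 5], seed=11 + seed)
            for cutoff in (4.0, 6.0, 9.0):
                panel = {r.key for r in pocket_panel(cx, cutoff)}
                lig = cx.ligand.heavy_coords()
                brute = set()
                for r in cx.receptor.residues:
                    rc = r.heavy_coords()
                    d = np.linalg.norm(rc[:, None, :] - lig[None, :, :], axis=2)
                    if len(rc) and d.min() <= cutoff:
                        brute.add(r.key)
                assert panel == brute


def _benzene(rotation_deg=0.0):
    coords = []
    for k in range(6):
        theta = math.radians(rotation_deg) + k * math.pi / 3
        coords.append([1.39 * math.cos(theta), 1.39 * math.sin(theta), 0.0])
    return LigandPose(["C"] * 6, np.array(coords), [0] * 6,
                      [(i, (i + 1) % 6, 12) for i in range(6)])


class TestPoseRmsd:
    def test_identity_is_zero(self):
        pose = _toy_ligand()
        assert pose_rmsd(pose, pose) == 0.0

    def test_rigid_translation_gives_exact_distance(self):
        pose = _toy_ligand()
        assert pose_rmsd(pose, pose.translated([1, 0, 0])) == pytest.approx(1.0)

    def test_benzene_sixty_degree_rotation(self):
        """A 60-degree ring flip is chemically identity: naive RMSD is large,
        the automorphism-corrected RMSD is zero."""
        a, b = _benzene(0.0), _benzene(60.0)
        assert pose_rmsd(a, b) > 1.0
        assert pose_rmsd(a, b, symmetry_aware=True) == pytest.approx(0.0, abs=1e-9)

    def test_automorphism_search_matches_exhaustive_enumeration(self):
        """Brute-force: all 720 vertex permutations of the hexagon, keeping the
        adjacency-preserving ones (the 12 dihedral symmetries)."""
        a, b = _benzene(0.0), _benzene(60.0)
        edges = {frozenset((i, (i + 1) % 6)) for i in range(6)}
        best = np.inf
        n_autos = 0
        for perm in itertools.permutations(range(6)):
            if all(frozenset((perm[i], perm[j])) in edges
                   for i, j in [(i, (i + 1) % 6) for i in range(6)]):
                n_autos += 1
                d = np.sqrt(np.mean(np.sum(
                    (a.coords - b.coords[list(perm)]) ** 2, axis=1)))
                best = min(best, d)
        assert n_autos == 12
        assert pose_rmsd(a, b, symmetry_aware=True) == pytest.approx(best, abs=1e-9)

    def test_different_molecules_rejected(self):
        with pytest.raises(ValueError):
            pose_rmsd(_toy_ligand(), _benzene())

    def test_pseudometric_on_random_triples(self):
        rng = np.random.default_rng(13)
        base = _toy_ligand()
        poses = [LigandPose(base.elements,
                            base.coords + rng.normal(0, 1.0, base.coords.shape),
                            base.formal_charges, base.bonds) for _ in range(9)]
        for pa, pb, pc in zip(poses[0::3], poses[1::3], poses[2::3]):
            dab = pose_rmsd(pa, pb)
            dba = pose_rmsd(pb, pa)
            assert dab == pytest.approx(dba)
            assert pose_rmsd(pa, pc) <= dab + pose_rmsd(pb, pc) + 1e-9


class TestSuperposeFrames:
    def _frames(self, n=4, sigma=0.0, seed=13):
        base, _ = simulate_complex("ionic", seed=1)
        rng = np.random.default_rng(seed)
        frames = [base]
        from siftkit.structures import _transform_complex
        from scipy.spatial.transform import Rotation
        for _ in range(n - 1):
            quat = rng.standard_normal(4)
            R = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
            t = rng.uniform(-10, 10, 3)
            moved = _transform_complex(base, R, t)
            if sigma > 0:
                jitter = ReceptorStructure([
                    type(r)(r.chain, r.number, r.aa_code,
                            [type(a)(a.name, a.element,
                                     tuple(np.asarray(a.coord)
                                           + rng.normal(0, sigma, 3)))
                             for a in r.atoms], r.icode, r.generic_number)
                    for r in moved.receptor.residues])
                moved = Complex(jitter, moved.ligand)
            frames.append(moved)
        return base, frames

    def test_identical_frames_identity_transforms(self):
        base, _ = simulate_complex("ionic", seed=1)
        aligned, transforms = superpose_frames([base, base, base])
        for R, t in transforms:
            np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
            np.testing.assert_allclose(t, 0.0, atol=1e-9)

    def test_rigid_motion_recovered_exactly(self):
        base, frames = self._frames(n=4, sigma=0.0)
        aligned, transforms = superpose_frames(frames)
        ref = aligned[0].receptor.alpha_carbons()
        for cx in aligned[1:]:
            sel = cx.receptor.alpha_carbons()
            rmsd = np.sqrt(np.mean(np.sum((sel - ref) ** 2, axis=1)))
            assert rmsd < 1e-8

    def test_noise_floor(self):
        sigma = 0.1
        base, frames = self._frames(n=6, sigma=sigma)
        aligned, _ = superpose_frames(frames)
        ref = aligned[0].receptor.alpha_carbons()
        for cx in aligned[1:]:
            sel = cx.receptor.alpha_carbons()
            rmsd = np.sqrt(np.mean(np.sum((sel - ref) ** 2, axis=1)))
            assert rmsd <= 3 * sigma

    def test_transforms_are_proper_rotations(self):
        base, frames = self._frames(n=5, sigma=0.05)
        _, transforms = superpose_frames(frames)
        for R, _ in transforms:
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)

    def test_too_few_reference_atoms_rejected(self):
        base, _ = simulate_complex("ionic", seed=1)
        with pytest.raises(ValueError):
            superpose_frames([base], reference_selection=lambda cx: np.zeros((2, 3)))
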