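"""Cα pairing, Kabsch superposition with rejection, polar contacts."""

import math

import gemmi
import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from sarm1tk import (
    CoordSet,
    kabsch,
    load_calpha,
    pair_residues,
    polar_contacts,
    superpose,
)
from sarm1tk.structure_compare import Atom, load_atoms, transformed_coords

from conftest import write_toy_pdb


def helix_coords(n, seed=0, jitter=0.0):
    """Cα-like helical trace, optionally perturbed."""
    t = np.arange(n) * 100.0 * math.pi / 180.0
    xyz = np.c_[2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)]
    if jitter:
        xyz = xyz + np.random.default_rng(seed).normal(0, jitter, xyz.shape)
    return xyz


def make_set(coords, start=1, chain="A", names=None):
    n = len(coords)
    return CoordSet(
        chain=chain,
        residue_numbers=np.arange(start, start + n),
        residue_names=names or ["ALA"] * n,
        coords=np.asarray(coords, float),
    )


class TestLoadCalpha:
    def test_small_file_read_in_order(self, tmp_path):
        path = write_toy_pdb(tmp_path / "toy.pdb", helix_coords(3))
        cs = load_calpha(path, "A")
        assert len(cs) == 3
        assert list(cs.residue_numbers) == [1, 2, 3]

    def test_residue_range_selection(self, tmp_path):
        path = write_toy_pdb(tmp_path / "toy.pdb", helix_coords(80), start_resnum=370)
        cs = load_calpha(path, "A", (373, 444))
        assert len(cs) == 72
        assert cs.residue_numbers[0] == 373
        assert cs.residue_numbers[-1] == 444

    def test_pdb_and_mmcif_give_identical_sets(self, tmp_path):
        pdb = write_toy_pdb(tmp_path / "toy.pdb", helix_coords(10))
        st = gemmi.read_structure(str(pdb))
        st.setup_entities()
        cif = tmp_path / "toy.cif"
        st.make_mmcif_document().write_file(str(cif))
        a = load_calpha(pdb, "A")
        b = load_calpha(cif, "A")
        assert np.allclose(a.coords, b.coords)
        assert list(a.residue_numbers) == list(b.residue_numbers)
        assert a.residue_names == b.residue_names

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "alt.pdb"
        path.write_text(text)
        cs = load_calpha(path, "A")
        assert cs.coords[0, 0] == pytest.approx(5.0)

    def test_missing_chain_errors(self, tmp_path):
        path = write_toy_pdb(tmp_path / "toy.pdb", helix_coords(3))
        with pytest.raises(ValueError, match="chain 'Z'"):
            load_calpha(path, "Z")

    def test_empty_range_errors(self, tmp_path):
        path = write_toy_pdb(tmp_path / "toy.pdb", helix_coords(3))
        with pytest.raises(ValueError, match="empty selection"):
            load_calpha(path, "A", (500, 600))


class TestPairResidues:
    def test_identical_numbering_full_pairing(self):
        a = make_set(helix_coords(20))
        b = make_set(helix_coords(20, jitter=0.1, seed=1))
        assert len(pair_residues(a, b)) == 20

    def test_interior_deletion_excluded(self):
        coords = helix_coords(20)
        a = make_set(coords)
        keep = [i for i in range(20) if i not in (5, 6, 7, 8, 9)]
        b = CoordSet(
            chain="A",
            residue_numbers=np.arange(1, 21)[keep],
            residue_names=["ALA"] * len(keep),
            coords=coords[keep],
        )
        pairs = pair_residues(a, b)
        assert len(pairs) == 15
        assert all(a.residue_numbers[i] not in (6, 7, 8, 9, 10) for i, _ in pairs)

    def test_disjoint_numbering_aligned_by_sequence(self):
        from sarm1tk.structure_compare import THREE_TO_ONE

        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        three = {v: k for k, v in THREE_TO_ONE.items()}
        resnames = [three[c] for c in seq]
        coords = helix_coords(len(seq))
        a = make_set(coords, start=1, names=resnames)
        b = make_set(coords, start=1001, names=resnames)
        pairs = pair_residues(a, b)
        assert pairs == [(i, i) for i in range(len(seq))]

    def test_too_few_pairs_errors(self):
        a = make_set(helix_coords(4), start=1)
        b = make_set(helix_coords(4), start=100)
        # 4 identical ALA residues align ambiguously; force the numbering path
        b2 = CoordSet("A", [1, 2], ["ALA", "ALA"], helix_coords(2))
        with pytest.raises(ValueError):
            pair_residues(make_set(helix_coords(2)), b2)


def brute_force_rmsd(mobile, target):
    """Oracle: minimise RMSD over rotations via coarse grid + simplex polish,
    never calling the SVD path."""
    mc, tc = mobile.mean(0), target.mean(0)
    p, q = mobile - mc, target - tc

    def rmsd_of(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        d = p @ r.T - q
        return math.sqrt(np.mean(np.sum(d * d, axis=1)))

    best = None
    grid = np.linspace(-math.pi, math.pi, 13)
    for ax in grid:
        for ay in grid:
            for az in grid:
                v = np.array([ax, ay, az])
                val = rmsd_of(v)
                if best is None or val < best[0]:
                    best = (val, v)
    sol = minimize(rmsd_of, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return float(sol.fun)


class TestSuperpose:
    def test_self_superposition_is_identity(self):
        a = make_set(helix_coords(30))
        res = superpose(a, a)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert res.paired_count == 30
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_rigid_motion_invariance(self):
        coords = helix_coords(30)
        a = make_set(coords)
        r = Rotation.random(random_state=3).as_matrix()
        b = make_set(coords @ r.T + np.array([4.0, -2.0, 9.0]))
        res = superpose(a, b)
        assert res.rmsd < 1e-8
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)
        assert res.rotation @ res.rotation.T == pytest.approx(np.eye(3), abs=1e-8)

    def test_rmsd_symmetry_without_rejection(self):
        a = make_set(helix_coords(25))
        b = make_set(helix_coords(25, jitter=0.4, seed=2))
        fwd = superpose(a, b, reject_cycles=0)
        rev = superpose(b, a, reject_cycles=0)
        assert fwd.rmsd == pytest.approx(rev.rmsd, abs=1e-9)

    def test_rejection_never_raises_rmsd(self):
        a = make_set(helix_coords(40))
        coords = helix_coords(40, jitter=0.3, seed=4)
        coords[37:] += 8.0  # displaced tail mimicking a mobile terminus
        b = make_set(coords)
        plain = superpose(a, b, reject_cycles=0)
        refined = superpose(a, b, reject_cycles=5, reject_sigma=2.0)
        assert refined.rmsd <= plain.rmsd
        assert refined.paired_count < plain.paired_count

    def test_kabsch_matches_rotation_grid_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            mobile = rng.normal(0, 2, (4, 3))
            target = rng.normal(0, 2, (4, 3))
            _, _, rmsd = kabsch(mobile, target)
            assert rmsd == pytest.approx(brute_force_rmsd(mobile, target), abs=1e-3)

    def test_transformed_coords_land_on_target(self):
        coords = helix_coords(12)
        a = make_set(coords)
        r = Rotation.random(random_state=8).as_matrix()
        b = make_set(coords @ r.T + 3.0)
        res = superpose(a, b)
        assert np.allclose(transformed_coords(a, res), b.coords, atol=1e-8)


class TestPolarContacts:
    @staticmethod
    def atom(name, element, pos):
        return Atom(name=name, element=element, pos=tuple(map(float, pos)))

    def test_distant_ligand_no_contacts(self):
        rec = [self.atom("N", "N", (0, 0, 0))]
        lig = [self.atom("O1", "O", (10, 0, 0))]
        assert polar_contacts(rec, lig) == []

    def test_carbon_pairs_filtered_out(self):
        rec = [self.atom("N", "N", (0, 0, 0)), self.atom("CA", "C", (0, 2.9, 0))]
        lig = [self.atom("O1", "O", (2.9, 0, 0))]
        found = polar_contacts(rec, lig)
        assert len(found) == 1
        assert found[0][0].element == "N"

    def test_cutoff_boundary(self):
        rec = [self.atom("N1", "N", (3.4, 0, 0)), self.atom("N2", "N", (0, 3.6, 0))]
        lig = [self.atom("O1", "O", (0, 0, 0))]
        found = polar_contacts(rec, lig, d_max=3.5)
        assert len(found) == 1
        assert found[0][2] == pytest.approx(3.4)

    def test_sorted_by_distance_and_requires_ligand(self):
        rec = [self.atom("N1", "N", (3.0, 0, 0)), self.atom("N2", "N", (2.0, 0, 0))]
        lig = [self.atom("O1", "O", (0, 0, 0))]
        found = polar_contacts(rec, lig)
        assert [c[2] for c in found] == sorted(c[2] for c in found)
        with pytest.raises(ValueError):
            polar_contacts(rec, [])

    def test_ligand_atoms_read_from_file(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2  O1  LIG A 900       1.000   0.000   0.000  1.00  0.00           O\n"
            "HETATM    3  N1  LIG A 900       2.000   0.000   0.000  1.00  0.00           N\n"
            "END\n"
        )
        path = tmp_path / "lig.pdb"
        path.write_text(text)
        atoms = load_atoms(path, "A", "LIG")
        assert {a.name for a in atoms} == {"O1", "N1"}
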