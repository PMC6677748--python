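import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trajectory
from ionflux.structures_io import AtomRole, Frame, Role, classify_atoms
from ionflux.trajectory_metrics import (
    contact_fraction,
    coordination_number,
    dihedral,
    helix_assignment,
    hydrophobic_thickness,
    kabsch_rmsd,
    nearest_ion_distance,
    residue_pair_distance,
)


def brute_force_contact_fraction(traj, residue_idx, probe_idx, cutoff):
    """Independent oracle: all-pairs distance scan per frame."""
    hits = 0
    for fr in traj.frames:
        found = False
        for i in residue_idx:
            for j in probe_idx:
                if np.linalg.norm(fr.coordinates[i] - fr.coordinates[j]) <= cutoff:
                    found = True
        if found:
            hits += 1
    return hits / traj.n_frames


def _binding_fixture(contact_frames, n_frames=10):
    """One ASP residue + one NA probe; probe 2 A away in contact frames,
    20 A away otherwise."""
    atoms = [("OD1", "ASP", 24, "B", "O"), ("NA", "NA", 99, "I", "NA")]
    frames = []
    for f in range(n_frames):
        probe = (2.0, 0.0, 0.0) if f in contact_frames else (20.0, 0.0, 0.0)
        frames.append([(0.0, 0.0, 0.0), probe])
    return make_trajectory(atoms, frames)


class TestContactFraction:
    def _run(self, traj, cutoff=3.5):
        roles = classify_atoms(traj)
        return contact_fraction(traj, [("B", 24)], [1], roles, cutoff=cutoff)

    def test_always_bound(self):
        traj = _binding_fixture(set(range(10)))
        assert self._run(traj).fractions[("B", 24, "ASP")] == 1.0

    def test_never_bound(self):
        traj = _binding_fixture(set())
        assert self._run(traj).fractions[("B", 24, "ASP")] == 0.0

    def test_four_of_ten(self):
        traj = _binding_fixture({0, 3, 5, 8})
        cmap = self._run(traj)
        assert cmap.fractions[("B", 24, "ASP")] == 0.4
        assert cmap.n_frames == 10

    def test_matches_brute_force_oracle(self, rng):
        atoms = [
            ("OD1", "ASP", 24, "B", "O"),
            ("OD2", "ASP", 24, "B", "O"),
            ("NA", "NA", 99, "I", "NA"),
        ]
        frames = [rng.uniform(-4, 4, size=(3, 3)) for _ in range(25)]
        traj = make_trajectory(atoms, frames)
        roles = classify_atoms(traj)
        cmap = contact_fraction(traj, [("B", 24)], [2], roles, cutoff=3.5)
        oracle = brute_force_contact_fraction(traj, [0, 1], [2], 3.5)
        assert cmap.fractions[("B", 24, "ASP")] == oracle

    def test_monotone_in_cutoff(self, rng):
        atoms = [("OD1", "ASP", 24, "B", "O"), ("NA", "NA", 99, "I", "NA")]
        frames = [rng.uniform(-6, 6, size=(2, 3)) for _ in range(30)]
        traj = make_trajectory(atoms, frames)
        roles = classify_atoms(traj)
        fracs = [
            contact_fraction(traj, [("B", 24)], [1], roles, cutoff=c)
            .fractions[("B", 24, "ASP")]
            for c in (1.0, 2.5, 3.5, 5.0, 8.0)
        ]
        assert fracs == sorted(fracs)

    def test_hydrogens_excluded(self):
        # H is 1 A from probe, heavy atom 20 A away: no contact
        atoms = [
            ("OD1", "ASP", 24, "B", "O"),
            ("HD1", "ASP", 24, "B", "H"),
            ("NA", "NA", 99, "I", "NA"),
        ]
        frames = [[(20.0, 0, 0), (1.0, 0, 0), (0.0, 0, 0)]]
        traj = make_trajectory(atoms, frames)
        roles = classify_atoms(traj)
        cmap = contact_fraction(traj, [("B", 24)], [2], roles)
        assert cmap.fractions[("B", 24, "ASP")] == 0.0

    def test_all_hydrogen_residue_errors(self):
        atoms = [("HD1", "ASP", 24, "B", "H"), ("NA", "NA", 99, "I", "NA")]
        traj = make_trajectory(atoms, [np.zeros((2, 3))])
        roles = classify_atoms(traj)
        with pytest.raises(ValueError, match="no non-hydrogen"):
            contact_fraction(traj, [("B", 24)], [1], roles)

    def test_empty_probe_errors(self, water_trio_traj):
        roles = classify_atoms(water_trio_traj)
        with pytest.raises(ValueError):
            contact_fraction(water_trio_traj, [("W", 1)], [], roles)


class TestCoordinationNumber:
    def test_isolated_ion(self):
        roles = [AtomRole(Role.ION, False, False)]
        frame = Frame(np.zeros((1, 3)), 0.0)
        assert coordination_number(frame, 0, roles) == 0

    def test_five_ligand_shell(self):
        """Two carboxylate O, one Thr O, two water O at 2.2-2.4 A."""
        xyz = np.array([
            (0.0, 0.0, 0.0),      # ion
            (2.2, 0.0, 0.0),      # OD1
            (-2.3, 0.0, 0.0),     # OD2
            (0.0, 2.2, 0.0),      # OG1
            (0.0, -2.4, 0.0),     # water O
            (0.0, 0.0, 2.3),      # water O
        ])
        roles = [
            AtomRole(Role.ION, False, False),
            AtomRole(Role.PROTEIN, True, False),
            AtomRole(Role.PROTEIN, True, False),
            AtomRole(Role.PROTEIN, True, False),
            AtomRole(Role.WATER, True, False),
            AtomRole(Role.WATER, True, False),
        ]
        assert coordination_number(Frame(xyz, 0.0), 0, roles) == 5

    def test_brute_force_random_radii(self, rng):
        n = 7
        radii = np.array([1.5, 2.0, 2.4, 2.6, 3.0, 5.0, 9.0])
        rng.shuffle(radii)
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        xyz = np.vstack([[0.0, 0.0, 0.0], dirs * radii[:, None]])
        roles = [AtomRole(Role.ION, False, False)] + [
            AtomRole(Role.PROTEIN, True, False) for _ in range(n)
        ]
        expected = int((radii <= 2.5).sum())
        assert coordination_number(Frame(xyz, 0.0), 0, roles) == expected
        assert expected == 3

    def test_rotation_translation_invariant(self, rng):
        xyz = rng.uniform(-3, 3, size=(6, 3))
        roles = [AtomRole(Role.ION, False, False)] + [
            AtomRole(Role.WATER, True, False) for _ in range(5)
        ]
        base = coordination_number(Frame(xyz, 0.0), 0, roles)
        theta = 0.7
        R = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        moved = xyz @ R.T + np.array([5.0, -3.0, 11.0])
        assert coordination_number(Frame(moved, 0.0), 0, roles) == base

    def test_hydrogen_and_lipid_never_counted(self):
        xyz = np.array([(0, 0, 0), (1.0, 0, 0), (0, 1.0, 0)], dtype=float)
        roles = [
            AtomRole(Role.ION, False, False),
            AtomRole(Role.PROTEIN, False, True),   # hydrogen
            AtomRole(Role.LIPID, True, False),     # lipid O
        ]
        assert coordination_number(Frame(xyz, 0.0), 0, roles) == 0

    def test_species_split_sums_to_total(self, rng):
        xyz = np.vstack([[0.0, 0.0, 0.0], rng.uniform(-3, 3, size=(8, 3))])
        roles = [AtomRole(Role.ION, False, False)]
        for i in range(8):
            roles.append(AtomRole(Role.PROTEIN if i % 2 else Role.WATER, True, False))
        frame = Frame(xyz, 0.0)
        total = coordination_number(frame, 0, roles, species="both")
        prot = coordination_number(frame, 0, roles, species="protein")
        wat = coordination_number(frame, 0, roles, species="water")
        assert prot + wat == total


class TestDistanceSeries:
    def test_constant_offset(self):
        atoms = [("OG1", "THR", 158, "A", "O"), ("NA", "NA", 99, "I", "NA")]
        frames = [[(0, 0, 0), (7.0, 0, 0)]] * 5
        traj = make_trajectory(atoms, frames)
        series = nearest_ion_distance(traj, 0, [1])
        np.testing.assert_allclose(series.values, 7.0)

    def test_min_over_two_ions(self):
        atoms = [
            ("OD1", "ASP", 24, "B", "O"),
            ("NA", "NA", 98, "I", "NA"),
            ("NA", "NA", 99, "I", "NA"),
        ]
        frames = [[(0, 0, 0), (2.9, 0, 0), (6.0, 0, 0)]]
        traj = make_trajectory(atoms, frames)
        assert nearest_ion_distance(traj, 0, [1, 2]).values[0] == pytest.approx(2.9)

    def test_random_walk_matches_brute_force(self, rng):
        atoms = [("OD1", "ASP", 24, "B", "O")] + [
            ("NA", "NA", 90 + i, "I", "NA") for i in range(4)
        ]
        frames = [rng.uniform(-10, 10, size=(5, 3)) for _ in range(20)]
        traj = make_trajectory(atoms, frames)
        series = nearest_ion_distance(traj, 0, [1, 2, 3, 4])
        for f, fr in enumerate(traj.frames):
            expected = min(
                np.linalg.norm(fr.coordinates[j] - fr.coordinates[0])
                for j in (1, 2, 3, 4)
            )
            assert series.values[f] == pytest.approx(expected)

    def test_empty_ion_set_errors(self, water_trio_traj):
        with pytest.raises(ValueError):
            nearest_ion_distance(water_trio_traj, 0, [])

    def test_pair_distance_zero(self):
        atoms = [("CA", "GLN", 54, "A", "C"), ("CA", "VAL", 149, "A", "C")]
        traj = make_trajectory(atoms, [[(1, 2, 3), (1, 2, 3)]])
        assert residue_pair_distance(traj, 0, 1).values[0] == 0.0

    def test_pair_distance_pythagoras(self):
        atoms = [("CA", "GLN", 54, "A", "C"), ("CA", "VAL", 149, "A", "C")]
        traj = make_trajectory(atoms, [[(0, 0, 0), (3, 4, 0)]])
        assert residue_pair_distance(traj, 0, 1).values[0] == pytest.approx(5.0)

    def test_pair_distance_brute_force(self, rng):
        atoms = [("CA", "GLN", 54, "A", "C"), ("CA", "VAL", 149, "A", "C")]
        frames = [rng.uniform(-30, 30, size=(2, 3)) for _ in range(12)]
        traj = make_trajectory(atoms, frames)
        series = residue_pair_distance(traj, 0, 1)
        for f, fr in enumerate(traj.frames):
            assert series.values[f] == pytest.approx(
                float(np.linalg.norm(fr.coordinates[0] - fr.coordinates[1])))

    def test_identical_indices_rejected(self, water_trio_traj):
        with pytest.raises(ValueError):
            residue_pair_distance(water_trio_traj, 2, 2)


class TestHydrophobicThickness:
    def _membrane(self, z_top, z_bottom, n_each=4, n_frames=1):
        atoms, coords = [], []
        for i in range(n_each):
            atoms.append(("P", "POPE", i + 1, "M", "P"))
            coords.append((float(i), 0.0, z_top))
        for i in range(n_each):
            atoms.append(("P", "POPE", n_each + i + 1, "M", "P"))
            coords.append((float(i), 0.0, z_bottom))
        return make_trajectory(atoms, [coords] * n_frames)

    def test_symmetric_case(self):
        traj = self._membrane(19.1, -19.1)
        res = hydrophobic_thickness(traj, markers=list(range(8)))
        assert res.mean == pytest.approx(38.2)
        assert res.sd == 0.0

    def test_asymmetric_single_frame(self):
        traj = self._membrane(20.0, -18.0)
        res = hydrophobic_thickness(traj, markers=list(range(8)))
        assert res.mean == pytest.approx(38.0)

    def test_noisy_leaflets_brute_force(self, rng):
        atoms = [("P", "POPE", i + 1, "M", "P") for i in range(10)]
        frames = []
        for _ in range(5):
            z_top = 19.0 + rng.normal(0, 0.5, 5)
            z_bot = -19.0 + rng.normal(0, 0.5, 5)
            frames.append([(0, 0, z) for z in np.concatenate([z_top, z_bot])])
        traj = make_trajectory(atoms, frames)
        res = hydrophobic_thickness(traj, top=list(range(5)),
                                    bottom=list(range(5, 10)))
        expected = []
        for fr in traj.frames:
            expected.append(fr.coordinates[:5, 2].mean() - fr.coordinates[5:, 2].mean())
        assert res.mean == pytest.approx(np.mean(expected))
        assert res.sd == pytest.approx(np.std(expected, ddof=1))

    def test_xy_translation_invariant(self):
        traj = self._membrane(19.1, -19.1)
        moved = make_trajectory(
            [(a.name, a.residue_name, a.residue_number, a.chain_id, a.element)
             for a in traj.topology],
            [traj.coords(0) + np.array([100.0, -40.0, 0.0])])
        res_a = hydrophobic_thickness(traj, markers=list(range(8)))
        res_b = hydrophobic_thickness(moved, markers=list(range(8)))
        assert res_a.mean == pytest.approx(res_b.mean)

    def test_z_flip_consistency(self):
        traj = self._membrane(20.0, -18.0)
        res = hydrophobic_thickness(traj, markers=list(range(8)))
        flipped = hydrophobic_thickness(traj.flipped_z(), markers=list(range(8)))
        # median-based leaflet assignment relabels leaflets: magnitude kept
        assert flipped.mean == pytest.approx(res.mean)
        explicit = hydrophobic_thickness(
            traj.flipped_z(), top=list(range(8 // 2)), bottom=list(range(4, 8)))
        assert explicit.mean == pytest.approx(-res.mean)

    def test_empty_leaflet_errors(self):
        traj = self._membrane(19.0, -19.0)
        with pytest.raises(ValueError):
            hydrophobic_thickness(traj, top=[0, 1], bottom=[])


def _helix_coords(n_res, phi=-57.0, psi=-47.0):
    """Build an ideal poly-backbone with the requested phi/psi via
    internal-coordinate chain construction (NeRF)."""
    # seed residue: N, CA, C in the xy plane (orientation is arbitrary)
    coords = [np.array([0.0, 0.0, 0.0]),
              np.array([1.46, 0.0, 0.0]),
              np.array([1.46 + 1.52 * np.cos(np.radians(68.0)),
                        1.52 * np.sin(np.radians(68.0)), 0.0])]

    def place(a, b, c, bond, angle, torsion):
        bc_n = (c - b) / np.linalg.norm(c - b)
        n = np.cross(b - a, bc_n)
        n /= np.linalg.norm(n)
        m = np.cross(n, bc_n)
        ang = np.radians(angle)
        tor = np.radians(torsion)
        d = np.array([
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ])
        return c + d[0] * bc_n + d[1] * m + d[2] * n

    specs = []
    for i in range(1, n_res):
        specs += [
            (1.33, 116.2, psi),     # C(i-1) -> N(i), torsion about CA-C = psi
            (1.46, 121.7, 180.0),   # N -> CA, omega
            (1.52, 111.0, phi),     # CA -> C, phi
        ]
    for bond, angle, torsion in specs:
        coords.append(place(coords[-3], coords[-2], coords[-1], bond, angle, torsion))
    return np.array(coords)


class TestHelixAssignment:
    def _traj_from_backbone(self, coords, n_res):
        atoms = []
        for i in range(n_res):
            for name in ("N", "CA", "C"):
                atoms.append((name, "ALA", i + 1, "A", {"N": "N", "CA": "C", "C": "C"}[name]))
        return make_trajectory(atoms, [coords])

    def test_ideal_helix_one_run(self):
        n = 12
        coords = _helix_coords(n, phi=-57.0, psi=-47.0)
        traj = self._traj_from_backbone(coords, n)
        result = helix_assignment(traj.frames[0], traj.topology)
        # interior residues (2..n-1) are assessable and helical
        interior = [("A", i) for i in range(2, n)]
        assert all(result.helical[k] for k in interior)
        assert len(result.runs) == 1
        chain, start, end = result.runs[0]
        assert end - start + 1 >= n - 2

    def test_extended_chain_not_helical(self):
        n = 8
        coords = _helix_coords(n, phi=180.0, psi=180.0)
        traj = self._traj_from_backbone(coords, n)
        result = helix_assignment(traj.frames[0], traj.topology)
        assert not any(result.helical.values())
        assert result.runs == []

    def test_three_residue_island_no_run(self):
        # a pure helix with only 3 assessable interior residues: no run
        short = _helix_coords(5, phi=-57.0, psi=-47.0)
        traj5 = self._traj_from_backbone(short, 5)
        res5 = helix_assignment(traj5.frames[0], traj5.topology)
        # window criterion holds for the 3 interior residues, but the
        # run-length rule (>= 4) vetoes them
        assert res5.runs == []
        assert not any(res5.helical.values())
        assert len(res5.helical) == 3

    def test_missing_backbone_excluded(self):
        atoms = [("CA", "ALA", 1, "A", "C")]
        traj = make_trajectory(atoms, [np.zeros((1, 3))])
        result = helix_assignment(traj.frames[0], traj.topology)
        assert ("A", 1) not in result.helical


class TestDihedral:
    def test_cis_is_zero(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_trans_is_180(self):
        d = dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0))
        assert abs(d) == pytest.approx(180.0)

    def test_right_angle(self):
        d = dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 0, 1))
        assert abs(d) == pytest.approx(90.0)


class TestKabschRMSD:
    def test_identical_sets(self, rng):
        pts = rng.uniform(-5, 5, size=(10, 3))
        assert kabsch_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(-5, 5, size=(10, 3))
        theta = 1.1
        R = np.array([
            [np.cos(theta), 0, np.sin(theta)],
            [0, 1, 0],
            [-np.sin(theta), 0, np.cos(theta)],
        ])
        moved = pts @ R.T + np.array([3.0, -7.0, 2.0])
        assert kabsch_rmsd(pts, moved) == pytest.approx(0.0, abs=1e-9)

    def test_two_point_closed_form(self):
        a = np.array([(0.0, 0.0, 0.0), (1.0, 0.0, 0.0)])
        b = np.array([(0.0, 0.0, 0.0), (2.0, 0.0, 0.0)])
        assert kabsch_rmsd(a, b) == pytest.approx(0.5)

    def test_symmetry(self, rng):
        a = rng.uniform(-5, 5, size=(6, 3))
        b = rng.uniform(-5, 5, size=(6, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(kabsch_rmsd(b, a), abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))

    @given(st.integers(min_value=3, max_value=12))
    @settings(max_examples=20, deadline=None)
    def test_nonnegative(self, n):
        rng = np.random.default_rng(n)
        a = rng.uniform(-5, 5, size=(n, 3))
        b = rng.uniform(-5, 5, size=(n, 3))
        assert kabsch_rmsd(a, b) >= 0.0
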