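import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from memims import memtraj
from memims.dxio import read_dx
from memims.memtraj import (
    Lipid,
    Topology,
    Trajectory,
    align_frames,
    assign_leaflets,
    count_hbonds,
    detect_contacts,
    phosphate_density,
    remove_clashing_lipids,
    select_annular_shell,
    thickness_map,
    threshold_density,
)
from memims.synthgen import gen_membrane


def brute_force_contacts(traj, cutoff, lipid_part="headgroup",
                         heavy_only=True):
    """O(N*M) oracle with explicit minimum-image distances."""
    top = traj.topology
    prot = [i for i in np.where(top.is_protein)[0]
            if not heavy_only or top.elements[i] != "H"]
    out = []
    for f in range(traj.n_frames):
        present = set()
        for lp in top.lipids:
            sel = lp.head_indices if lipid_part == "headgroup" else lp.atom_indices
            sel = [i for i in sel if not heavy_only or top.elements[i] != "H"]
            if not sel:
                continue
            dmin = np.inf
            for i in sel:
                for j in prot:
                    d = traj.coords[f][i] - traj.coords[f][j]
                    if traj.box is not None:
                        d -= np.round(d / traj.box) * traj.box
                    dmin = min(dmin, float(np.linalg.norm(d)))
            if dmin <= cutoff:
                present.add(lp.lipid_id)
        out.append(present)
    return out


def random_system(rng, n_prot=20, n_lip=8, n_frames=2, box=None):
    """A random point system with simple 3-atom lipids."""
    names, elements, resnames, resids, chains = [], [], [], [], []
    L = 30.0
    for i in range(n_prot):
        names.append("CA"); elements.append("C"); resnames.append("ALA")
        resids.append(i); chains.append("A")
    lipids = []
    for k in range(n_lip):
        start = n_prot + 3 * k
        for a, el in enumerate(["P", "O", "C"]):
            names.append(el); elements.append(el); resnames.append("LIP")
            resids.append(100 + k); chains.append("L")
        lipids.append(Lipid(
            lipid_id=k,
            atom_indices=np.arange(start, start + 3),
            head_indices=np.arange(start, start + 2),
            phosphorus_index=start,
        ))
    n_atoms = n_prot + 3 * n_lip
    coords = rng.uniform(0, L, (n_frames, n_atoms, 3))
    top = Topology(names, elements, resnames, np.array(resids), chains,
                   np.array([r == "ALA" for r in resnames]), lipids)
    return Trajectory(top, coords,
                      box=np.array([L, L, L]) if box else None,
                      times=np.arange(n_frames) * 0.1)


class TestAlignment:
    def test_rigid_transforms_align_to_zero_rmsd(self, rng):
        traj = random_system(rng, n_frames=1)
        base = traj.coords[0]
        frames = [base]
        for k in range(3):
            R = Rotation.random(rng=rng).as_matrix()
            frames.append(base @ R.T + rng.normal(0, 5, 3))
        traj = Trajectory(traj.topology, np.stack(frames), box=None)
        aligned = align_frames(traj)
        for f in range(1, aligned.n_frames):
            assert memtraj.rmsd(aligned.coords[f], base) < 1e-8

    def test_planted_rotation_recovered(self, rng):
        traj = random_system(rng, n_frames=1)
        base = traj.coords[0]
        R = Rotation.from_euler("zyx", [0.5, 0.2, 1.0]).as_matrix()
        traj2 = Trajectory(traj.topology, np.stack([base, base @ R.T]), box=None)
        aligned = align_frames(traj2)
        # aligning applies R^T, restoring the original coordinates
        np.testing.assert_allclose(aligned.coords[1], base, atol=1e-8)

    def test_distances_preserved(self, rng):
        traj = random_system(rng, n_frames=3)
        aligned = align_frames(traj)
        for f in range(traj.n_frames):
            d0 = np.linalg.norm(
                traj.coords[f][:10, None] - traj.coords[f][None, :10], axis=2)
            d1 = np.linalg.norm(
                aligned.coords[f][:10, None] - aligned.coords[f][None, :10],
                axis=2)
            np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_idempotent(self, rng):
        traj = random_system(rng, n_frames=4)
        once = align_frames(traj)
        twice = align_frames(once)
        assert np.abs(twice.coords - once.coords).max() < 1e-8

    def test_too_few_reference_atoms(self, rng):
        traj = random_system(rng)
        mask = np.zeros(traj.n_atoms, dtype=bool)
        mask[:2] = True
        with pytest.raises(ValueError, match="3 reference"):
            align_frames(traj, mask)


class TestContacts:
    def _system_with_gap(self, gap):
        """One protein atom at origin, one lipid head O at distance ``gap``."""
        names = ["CA", "P", "O", "C"]
        elements = ["C", "P", "O", "C"]
        resnames = ["ALA", "LIP", "LIP", "LIP"]
        lip = Lipid(0, np.arange(1, 4), np.arange(1, 3), 1)
        top = Topology(names, elements, resnames, np.arange(4),
                       ["A", "L", "L", "L"],
                       np.array([True, False, False, False]), [lip])
        coords = np.array([[
            [0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [gap, 0.0, 0.0],
            [12.0, 0.0, 0.0],
        ]])
        return Trajectory(top, coords, box=None)

    def test_cutoff_inclusive_at_215(self):
        ct = detect_contacts(self._system_with_gap(2.15), cutoff=2.15)
        assert ct.per_frame[0] == {0}

    def test_216_no_contact(self):
        ct = detect_contacts(self._system_with_gap(2.16), cutoff=2.15)
        assert ct.per_frame[0] == set()

    @pytest.mark.parametrize("use_box", [False, True])
    def test_matches_brute_force_on_random_systems(self, use_box):
        rng = np.random.default_rng(99 + use_box)
        for trial in range(25):
            traj = random_system(rng, n_prot=15, n_lip=6, n_frames=2,
                                 box=use_box)
            cutoff = float(rng.uniform(2.0, 6.0))
            part = "headgroup" if trial % 2 == 0 else "whole"
            fast = detect_contacts(traj, cutoff=cutoff, lipid_part=part)
            slow = brute_force_contacts(traj, cutoff, lipid_part=part)
            assert fast.per_frame == slow

    def test_occupancy_definition(self, small_membrane):
        traj, gt = small_membrane
        ct = detect_contacts(traj)
        for lid, occ in ct.occupancy.items():
            n_in = sum(1 for s in ct.per_frame if lid in s)
            assert occ == n_in / traj.n_frames

    def test_no_lipids_empty_table(self, rng):
        traj = random_system(rng, n_lip=0)
        ct = detect_contacts(traj)
        assert ct.lipid_ids == []


class TestClashRemoval:
    def test_planted_clashes_removed_exactly(self, small_membrane):
        traj, gt = small_membrane
        out, removed = remove_clashing_lipids(traj)
        assert sorted(removed) == sorted(gt.params["clash_ids"])
        assert len(out.topology.lipids) == len(traj.topology.lipids) - len(removed)

    def test_all_far_zero_removed(self, flat_membrane):
        traj, gt = flat_membrane
        # flat membrane has no planted clashes but does have shell contacts
        _, removed = remove_clashing_lipids(traj, cutoff=0.5)
        assert removed == []

    def test_close_atom_is_removed(self, rng):
        traj = random_system(rng, n_prot=1, n_lip=1, n_frames=1)
        traj.coords[0, 0] = [0, 0, 0]
        traj.coords[0, 1:4] = [[0.3, 0, 0], [5, 0, 0], [6, 0, 0]]
        _, removed = remove_clashing_lipids(traj)
        assert removed == [0]

    def test_atom_indexing_consistent_after_removal(self, small_membrane):
        traj, gt = small_membrane
        out, removed = remove_clashing_lipids(traj)
        for lp in out.topology.lipids:
            assert out.topology.elements[lp.phosphorus_index] == "P"


class TestLeaflets:
    def test_flat_bilayer_perfect_assignment(self, flat_membrane):
        traj, gt = flat_membrane
        tags = assign_leaflets(traj)
        cz = gt.params["membrane_center_z"]
        for lp in traj.topology.lipids:
            z = traj.coords[0][lp.phosphorus_index][2]
            assert tags[lp.lipid_id] == ("upper" if z > cz else "lower")

    def test_midplane_tie_rule(self):
        names = ["P", "P", "P"]
        lipids = [Lipid(i, np.array([i]), np.array([i]), i) for i in range(3)]
        top = Topology(names, ["P"] * 3, ["LIP"] * 3, np.arange(3),
                       ["L"] * 3, np.zeros(3, dtype=bool), lipids)
        # midplane converges to 0; the tied lipid is nearer the upper mean
        coords = np.array([[[0, 0, 8.0], [0, 0, -8.0], [0, 0, 0.0]]])
        traj = Trajectory(top, coords)
        tags = assign_leaflets(traj)
        assert tags[0] == "upper" and tags[1] == "lower"
        assert tags[2] in ("upper", "lower")

    def test_planted_split_recovered(self, small_membrane):
        traj, gt = small_membrane
        tags = assign_leaflets(traj)
        shell = gt.params["shell"]
        for lid_str, leaflet in shell.items():
            assert tags[int(lid_str)] == leaflet

    def test_too_few_lipids(self, rng):
        traj = random_system(rng, n_lip=1)
        with pytest.raises(ValueError):
            assign_leaflets(traj)


class TestShellSelection:
    def test_planted_23_shell_with_split(self, small_membrane):
        traj, gt = small_membrane
        traj2, _ = remove_clashing_lipids(traj)
        tags = assign_leaflets(traj2)
        ct = detect_contacts(traj2)
        shell = select_annular_shell(ct, occupancy_min=0.9, leaflets=tags)
        assert shell.n_lipids == 23
        assert shell.per_leaflet == {"upper": 13, "lower": 10}
        assert set(shell.lipid_ids) == {int(k) for k in gt.params["shell"]}

    def test_occupancy_zero_selects_all_contacting(self, small_membrane):
        traj, gt = small_membrane
        ct = detect_contacts(traj)
        shell = select_annular_shell(ct, occupancy_min=0.0)
        ever = {lid for s in ct.per_frame for lid in s}
        assert set(shell.lipid_ids) == ever

    def test_empty_shell_allowed(self, rng):
        traj = random_system(rng, n_prot=1, n_lip=2, n_frames=2)
        traj.coords[:, 0] = [0, 0, 0]
        traj.coords[:, 1:] = 100.0 + traj.coords[:, 1:] * 0.01
        ct = detect_contacts(traj, use_pbc=False)
        shell = select_annular_shell(ct, occupancy_min=1.0)
        assert shell.lipid_ids == []

    def test_deterministic_ordering(self, small_membrane):
        traj, gt = small_membrane
        ct = detect_contacts(traj)
        shell = select_annular_shell(ct, occupancy_min=0.3)
        occ = [shell.occupancies[lid] for lid in shell.lipid_ids]
        assert occ == sorted(occ, reverse=True) or all(
            (o1 > o2) or (o1 == o2 and l1 < l2)
            for (o1, l1), (o2, l2) in zip(
                zip(occ, shell.lipid_ids), zip(occ[1:], shell.lipid_ids[1:]))
        )

    def test_separation_02_recovers_planted_set(self):
        traj, gt = gen_membrane(n_lipids=60, box=(100, 100, 80), n_frames=10,
                                n_transient=6, transient_occupancy=0.7,
                                seed=11)
        ct = detect_contacts(traj)
        shell = select_annular_shell(ct, occupancy_min=0.9)
        assert set(shell.lipid_ids) == {int(k) for k in gt.params["shell"]}


class TestDensity:
    def _point_traj(self, pts):
        pts = np.asarray(pts, dtype=float)
        n = len(pts)
        lipids = [Lipid(i, np.array([i]), np.array([i]), i) for i in range(n)]
        top = Topology(["P"] * n, ["P"] * n, ["LIP"] * n, np.arange(n),
                       ["L"] * n, np.zeros(n, dtype=bool), lipids)
        traj = Trajectory(top, pts[None, :, :])
        ct = memtraj.ContactTable(list(range(n)), [set(range(n))], 1)
        return traj, ct

    def test_single_point(self):
        traj, ct = self._point_traj([[5.0, 5.0, 5.0]])
        grid = phosphate_density(traj, ct, bandwidth=1.0, spacing=0.5)
        assert grid.integral() == pytest.approx(1.0, rel=0.01)
        np.testing.assert_allclose(grid.argmax_position(), [5.0, 5.0, 5.0],
                                   atol=0.51)

    def test_n_points_integral(self, rng):
        pts = rng.normal(0, 3, (40, 3))
        traj, ct = self._point_traj(pts)
        grid = phosphate_density(traj, ct, spacing=0.8)
        assert grid.integral() == pytest.approx(40.0, rel=0.01)

    @pytest.mark.parametrize("bandwidth,spacing", [
        (0.8, 0.4), (1.5, 0.75), (None, 0.5), (2.5, 1.0),
    ])
    def test_mass_conservation_across_settings(self, rng, bandwidth, spacing):
        pts = rng.normal(0, 4, (25, 3))
        traj, ct = self._point_traj(pts)
        grid = phosphate_density(traj, ct, bandwidth=bandwidth, spacing=spacing)
        assert grid.integral() == pytest.approx(25.0, rel=0.01)

    def test_planted_cluster_argmax(self):
        traj, gt = gen_membrane(n_lipids=40, box=(80, 80, 80), n_frames=6,
                                n_shell_upper=1, n_shell_lower=1,
                                n_transient=0, seed=12)
        ct = detect_contacts(traj)
        grid = phosphate_density(traj, ct, spacing=1.0)
        shell_ids = [int(k) for k in gt.params["shell"]]
        p_positions = np.array([
            traj.coords[0][traj.topology.lipid_by_id(l).phosphorus_index]
            for l in shell_ids
        ])
        argmax = grid.argmax_position()
        dists = np.linalg.norm(p_positions - argmax, axis=1)
        assert dists.min() <= max(grid.bandwidth.max(), grid.spacing)

    def test_zero_points_error(self):
        traj, ct = self._point_traj([[0.0, 0.0, 0.0]])
        empty = memtraj.ContactTable([0], [set()], 1)
        with pytest.raises(ValueError, match="no contact"):
            phosphate_density(traj, empty)


class TestThresholdDensity:
    def test_cutoff_above_max_empty(self):
        traj, ct = TestDensity()._point_traj([[0.0, 0.0, 0.0]])
        grid = phosphate_density(traj, ct, bandwidth=1.0, spacing=0.5)
        res = threshold_density(grid, cutoff=grid.values.max() * 2)
        assert not res["mask"].any()
        assert res["regions"] == []

    def test_cutoff_zero_full_support(self):
        traj, ct = TestDensity()._point_traj([[0.0, 0.0, 0.0]])
        grid = phosphate_density(traj, ct, bandwidth=1.0, spacing=0.5)
        res = threshold_density(grid, cutoff=0.0)
        assert res["mask"].all()
        assert len(res["regions"]) == 1

    def test_two_separated_clusters(self):
        traj, ct = TestDensity()._point_traj(
            [[0.0, 0.0, 0.0], [30.0, 30.0, 30.0]])
        grid = phosphate_density(traj, ct, bandwidth=1.0, spacing=1.0)
        res = threshold_density(grid, cutoff=2e-5)
        assert len(res["regions"]) == 2


class TestThickness:
    def test_flat_bilayer_uniform(self, flat_membrane):
        traj, gt = flat_membrane
        assign_leaflets(traj)
        tm = thickness_map(traj)
        vals = tm.thickness.compressed()
        assert np.all(np.abs(vals - 38.0) < 0.5)

    def test_planted_depression_minimum(self):
        traj, gt = gen_membrane(
            n_lipids=320, box=(80, 80, 80), n_frames=4, n_transient=0,
            depression={"center": (60.0, 60.0), "depth": 8.0, "sigma": 12.0},
            seed=13,
        )
        assign_leaflets(traj)
        tm = thickness_map(traj, grid_spacing=4.0)
        cx, cy = gt.params["depression"]["center"]
        assert abs(tm.min_location[0] - cx) <= 4.0
        assert abs(tm.min_location[1] - cy) <= 4.0
        assert tm.min_thickness == pytest.approx(
            gt.params["min_thickness"], abs=0.5)

    def test_xy_translation_invariance_periodic(self, flat_membrane):
        traj, gt = flat_membrane
        assign_leaflets(traj)
        tm1 = thickness_map(traj, grid_spacing=4.0)
        shifted = Trajectory(
            traj.topology,
            traj.coords + np.array([8.0, 12.0, 0.0]),  # multiples of spacing
            box=traj.box, times=traj.times,
        )
        tm2 = thickness_map(shifted, grid_spacing=4.0)
        rolled = np.roll(np.roll(tm1.thickness.filled(np.nan), 2, axis=0),
                         3, axis=1)
        np.testing.assert_allclose(
            tm2.thickness.filled(np.nan), rolled, atol=1e-8, equal_nan=True)

    def test_requires_leaflets(self, small_membrane):
        traj, gt = gen_membrane(n_lipids=40, n_frames=2, seed=14)
        with pytest.raises(ValueError, match="assign_leaflets"):
            thickness_map(traj)

    def test_masked_not_zero_filled(self, flat_membrane):
        traj, gt = flat_membrane
        assign_leaflets(traj)
        tm = thickness_map(traj, grid_spacing=2.0)
        assert tm.thickness.mask.any()
        assert np.all(tm.thickness.compressed() > 0)


class TestHBonds:
    def _triplet_system(self, d_da=2.8, angle=180.0):
        """Protein acceptor O, lipid donor O-H at given geometry."""
        theta = np.deg2rad(180.0 - angle)
        acc = np.array([0.0, 0.0, 0.0])
        hyd = np.array([1.8, 0.0, 0.0])
        don = hyd + np.array([np.cos(theta), np.sin(theta), 0.0])
        don = hyd + (don - hyd) / np.linalg.norm(don - hyd) * 1.0
        # rescale so that |don - acc| = d_da
        scale = d_da / np.linalg.norm(don - acc)
        names = ["O", "OD", "HD", "C"]
        elements = ["O", "O", "H", "C"]
        resnames = ["ALA", "LIP", "LIP", "LIP"]
        lip = Lipid(0, np.arange(1, 4), np.arange(1, 4), None)
        top = Topology(names, elements, resnames, np.arange(4),
                       ["A", "L", "L", "L"],
                       np.array([True, False, False, False]), [lip])
        coords = np.array([[acc, don * scale, hyd * scale, [9.0, 9.0, 9.0]]])
        return Trajectory(top, coords)

    def test_ideal_geometry_counted(self):
        traj = self._triplet_system(d_da=2.8, angle=180.0)
        stats = count_hbonds(traj, [0])
        assert stats.mean_per_lipid == 1.0

    def test_long_distance_not_counted(self):
        traj = self._triplet_system(d_da=4.0, angle=180.0)
        stats = count_hbonds(traj, [0])
        assert stats.mean_per_lipid == 0.0

    def test_bad_angle_not_counted(self):
        traj = self._triplet_system(d_da=2.8, angle=120.0)
        stats = count_hbonds(traj, [0])
        assert stats.mean_per_lipid == 0.0

    def test_planted_count_recovered_exactly(self, small_membrane):
        traj, gt = small_membrane
        traj2, _ = remove_clashing_lipids(traj)
        ct = detect_contacts(traj2)
        shell = select_annular_shell(ct, occupancy_min=0.9)
        stats = count_hbonds(traj2, shell.lipid_ids)
        assert stats.mean_per_lipid == pytest.approx(
            float(gt.params["hbonds_per_lipid"]))
        for lid, mean in stats.per_lipid_means().items():
            assert mean == pytest.approx(float(gt.params["hbonds_per_lipid"]))

    def test_no_polar_atoms_error(self, rng):
        names = ["CA", "C", "C", "C"]
        lip = Lipid(0, np.arange(1, 4), np.arange(1, 4), None)
        top = Topology(names, ["C"] * 4, ["ALA", "LIP", "LIP", "LIP"],
                       np.arange(4), ["A", "L", "L", "L"],
                       np.array([True, False, False, False]), [lip])
        traj = Trajectory(top, rng.normal(0, 5, (1, 4, 3)))
        with pytest.raises(ValueError, match="polar"):
            count_hbonds(traj, [0])


class TestTrajectoryIO:
    def test_multimodel_pdb_round_trip(self, tmp_path, small_membrane):
        traj, gt = small_membrane
        p = tmp_path / "mem.pdb"
        traj.to_multimodel_pdb(p)
        back = Trajectory.from_multimodel_pdb(p)
        assert back.n_frames == traj.n_frames
        assert back.n_atoms == traj.n_atoms
        assert len(back.topology.lipids) == len(traj.topology.lipids)
        np.testing.assert_allclose(back.coords, np.round(traj.coords, 3),
                                   atol=1e-6)
        # analyses agree on the round-tripped trajectory
        ct1 = detect_contacts(traj)
        ct2 = detect_contacts(back)
        occ1 = ct1.occupancy
        occ2 = {lid: occ for lid, occ in ct2.occupancy.items()}
        assert sorted(occ1.values()) == sorted(occ2.values())

    def test_dx_round_trip(self, tmp_path):
        traj, ct = TestDensity()._point_traj([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        grid = phosphate_density(traj, ct, bandwidth=1.2, spacing=0.8)
        p = tmp_path / "d.dx"
        grid.write_dx(p)
        values, origin, spacing = read_dx(p)
        np.testing.assert_allclose(values, grid.values, rtol=1e-6)
        np.testing.assert_allclose(origin, grid.origin, atol=1e-5)
        np.testing.assert_allclose(spacing, grid.spacing, atol=1e-9)
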