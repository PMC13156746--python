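"""Superposition, RMSD/RMSF/Rg, maps, H-bonds, dihedrals and SASA."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from actintools import model_io, synthetic
from actintools.ensemble import (
    HBondCriteria,
    difference_map,
    dihedral,
    dihedral_series,
    hydrogen_bonds,
    per_residue_rmsd,
    radius_of_gyration,
    residue_distance_map,
    rmsd_correlation_matrix,
    rmsd_series,
    rmsf,
    sasa,
    superpose,
)
from tests.conftest import build_system, make_trajectory, random_rotation


class TestSuperposition:
    def test_identical_structures_have_zero_rmsd(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 5, (10, 3))
        _, _, r = superpose(pts, pts)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rotated_copy_fits_back_exactly(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 5, (12, 3))
        moved = pts @ random_rotation(rng).T + [3.0, -1.0, 7.0]
        rot, trans, r = superpose(moved, pts)
        assert r < 1e-6
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_rotation_search(self):
        """Kabsch equals direct minimization over rotations (grid+refine)."""
        rng = np.random.default_rng(2)
        a = rng.normal(0, 3, (4, 3))
        b = rng.normal(0, 3, (4, 3))
        _, _, kabsch_rmsd = superpose(a, b)

        a0 = a - a.mean(axis=0)
        b0 = b - b.mean(axis=0)

        def cost(angles):
            rot = Rotation.from_euler("xyz", angles).as_matrix()
            return np.sqrt(np.mean(np.sum((a0 @ rot.T - b0) ** 2, axis=1)))

        best = np.inf
        for sx in np.linspace(-np.pi, np.pi, 7):
            for sy in np.linspace(-np.pi / 2, np.pi / 2, 5):
                for sz in np.linspace(-np.pi, np.pi, 7):
                    res = minimize(cost, [sx, sy, sz], method="Nelder-Mead")
                    best = min(best, res.fun)
        assert kabsch_rmsd == pytest.approx(best, abs=1e-6)

    def test_collinear_selection_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line + 1.0)


class TestRMSDSeries:
    def _simple_system(self):
        pts = [[0, 0, 0], [3, 0, 0], [3, 3, 0], [0, 3, 3], [1, 1, 5]]
        return build_system(
            [
                (i + 1, "ALA", [("CA", "C", [float(c) for c in p])])
                for i, p in enumerate(pts)
            ]
            + [(10, "GLY", [("CA", "C", [10.0, 10.0, 0.0])])]
        )

    def test_constant_trajectory_is_zero(self):
        system = self._simple_system()
        base = system.coordinates()
        traj = make_trajectory(system, np.stack([base] * 4))
        out = rmsd_series(traj, base, np.arange(6))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_global_translation_removed_by_fit(self):
        system = self._simple_system()
        base = system.coordinates()
        traj = make_trajectory(system, np.stack([base, base + 1.0]))
        out = rmsd_series(traj, base, np.arange(6))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_ligand_displacement_measured_after_protein_fit(self):
        system = self._simple_system()
        base = system.coordinates()
        moved = base.copy()
        moved[5] += [0.0, 0.0, 2.0]  # displace the off-axis atom only
        traj = make_trajectory(system, np.stack([base, moved]))
        out = rmsd_series(
            traj, base, fit_selection=np.arange(5),
            measure_selection=np.array([5]),
        )
        assert out[1] == pytest.approx(2.0, abs=1e-9)

    def test_empty_selection_rejected(self):
        system = self._simple_system()
        traj = make_trajectory(system, np.stack([system.coordinates()] * 2))
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(traj, system.coordinates(), np.array([], dtype=int))


class TestRMSF:
    def test_static_trajectory_gives_zero_rmsf(self, scaffold, scaffold_view):
        base = scaffold.coordinates()
        traj = make_trajectory(scaffold, np.stack([base] * 3))
        out = rmsf(traj, scaffold_view)
        assert max(abs(v) for v in out.values.values()) < 1e-9

    def test_single_frame_rejected(self, scaffold, scaffold_view):
        traj = make_trajectory(scaffold, scaffold.coordinates()[None])
        with pytest.raises(ValueError, match="2 frames"):
            rmsf(traj, scaffold_view)

    def test_isotropic_gaussian_recovers_sigma_sqrt3(self, scaffold, scaffold_view):
        """RMSF of an isotropic Gaussian of width sigma is sigma*sqrt(3)."""
        sigma = 0.8
        motion = synthetic.MotionModel(noise=synthetic.NoiseSpec(sigma_A=sigma))
        traj, _ = synthetic.generate_trajectory(scaffold, motion, 2000, seed=5)
        out = rmsf(traj, scaffold_view)
        values = out.as_array()
        assert np.median(values) == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_delta_rmsf_is_antisymmetric(self, scaffold, scaffold_view):
        motion = synthetic.MotionModel(noise=synthetic.NoiseSpec(sigma_A=0.5))
        t1, _ = synthetic.generate_trajectory(scaffold, motion, 50, seed=1)
        t2, _ = synthetic.generate_trajectory(scaffold, motion, 50, seed=2)
        a = rmsf(t1, scaffold_view)
        b = rmsf(t2, scaffold_view)
        ab = difference_map(a, b)
        ba = difference_map(b, a)
        np.testing.assert_allclose(ab.as_array(), -ba.as_array(), atol=1e-12)


class TestRadiusOfGyration:
    def test_point_mass_is_zero(self):
        system = build_system([(1, "ALA", [("CA", "C", [1.0, 2.0, 3.0])])])
        traj = make_trajectory(system, np.stack([system.coordinates()] * 2))
        np.testing.assert_allclose(
            radius_of_gyration(traj, np.array([0])), 0.0, atol=1e-12
        )

    def test_cube_corners_analytic(self):
        corners = np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
            dtype=float,
        )
        system = build_system(
            [(i + 1, "ALA", [("CA", "C", c)]) for i, c in enumerate(corners)]
        )
        traj = make_trajectory(system, corners[None])
        rg = radius_of_gyration(traj, np.arange(8))
        assert rg[0] == pytest.approx(np.sqrt(3.0), abs=1e-12)

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 4, (9, 3))
        system = build_system(
            [(i + 1, "ALA", [("CA", "C", c)]) for i, c in enumerate(pts)]
        )
        traj = make_trajectory(system, np.stack([pts, 2 * pts]))
        rg = radius_of_gyration(traj, np.arange(9))
        assert rg[1] == pytest.approx(2 * rg[0], rel=1e-12)


class TestPerResidueMaps:
    def test_identical_structures_give_zero_map(self, scaffold, scaffold_view):
        base = scaffold.coordinates()
        out = per_residue_rmsd([base, base], base, scaffold_view)
        assert max(abs(v) for v in out.values.values()) < 1e-9

    def test_uniform_displacement_of_one_residue(self, scaffold, scaffold_view):
        base = scaffold.coordinates()
        moved = base.copy()
        idx = scaffold_view.ca_indices[375]
        # displace along the 374->375 direction so the global CA fit is
        # negligibly perturbed (1 of 375 atoms)
        moved[idx] += [0.0, 0.0, 2.0]
        out = per_residue_rmsd([moved], base, scaffold_view)
        assert out[("A", 375)] == pytest.approx(2.0, abs=0.02)

    def test_difference_with_itself_is_zero(self, scaffold, scaffold_view):
        base = scaffold.coordinates()
        m = per_residue_rmsd([base + 0.5], base, scaffold_view)
        d = difference_map(m, m)
        assert max(abs(v) for v in d.values.values()) == 0.0

    def test_disjoint_keys_rejected(self):
        from actintools.ensemble import PerResidueMap

        with pytest.raises(ValueError, match="no residue keys"):
            difference_map(
                PerResidueMap({("A", 1): 1.0}), PerResidueMap({("B", 2): 1.0})
            )


class TestRMSDCorrelation:
    def _trajectory_with_series(self, series_map):
        """Build a trajectory whose per-residue displacement series are
        prescribed (each residue moves along its own unit direction)."""
        n_frames = len(next(iter(series_map.values())))
        nums = sorted(series_map)
        base_pos = {
            n: np.array([10.0 * i, 0.0, 0.0]) for i, n in enumerate(nums)
        }
        # three anchor residues pin the superposition
        anchors = {900: [0, 100, 0], 901: [50, 120, 0], 902: [0, 140, 50]}
        specs = [
            (n, "ALA", [("CA", "C", base_pos[n])]) for n in nums
        ] + [(n, "GLY", [("CA", "C", p)]) for n, p in anchors.items()]
        system = build_system(specs)
        base = system.coordinates()
        frames = np.stack([base] * n_frames)
        for i, n in enumerate(nums):
            for t in range(n_frames):
                frames[t, i, 1] = series_map[n][t]
        return system, make_trajectory(system, frames)

    def test_proportional_series_correlate_perfectly(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 2.0, 1.0])
        system, traj = self._trajectory_with_series({1: x, 2: 2 * x})
        view = model_io.ProtomerView(system, "A")
        corr, keys = rmsd_correlation_matrix(traj, view)
        i, j = keys.index(("A", 1)), keys.index(("A", 2))
        assert corr[i, j] == pytest.approx(1.0, abs=1e-6)

    def test_antiphase_series_anticorrelate(self):
        # both displacement series start at 0 (distance to the t=0
        # position), so anticorrelation shows as a strongly negative r
        # matching the Pearson coefficient of the planted series
        x = np.array(
            [0., 1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1, 2, 3, 4, 5, 6, 5, 4, 3]
        )
        y = np.array(
            [0., 6, 5, 4, 3, 2, 1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1, 2, 3, 4]
        )
        system, traj = self._trajectory_with_series({1: x, 2: y})
        view = model_io.ProtomerView(system, "A")
        corr, keys = rmsd_correlation_matrix(traj, view)
        i, j = keys.index(("A", 1)), keys.index(("A", 2))
        expected = np.corrcoef(x, y)[0, 1]
        assert expected < -0.5
        # the frame-0 fit runs over all five CAs, so the realized series
        # deviate slightly from the planted ones
        assert corr[i, j] == pytest.approx(expected, abs=0.2)
        assert corr[i, j] < -0.5

    def test_independent_series_nearly_uncorrelated(self, scaffold, scaffold_view):
        motion = synthetic.MotionModel(noise=synthetic.NoiseSpec(sigma_A=0.5))
        traj, _ = synthetic.generate_trajectory(scaffold, motion, 2000, seed=9)
        corr, keys = rmsd_correlation_matrix(traj, scaffold_view)
        i, j = keys.index(("A", 100)), keys.index(("A", 300))
        assert abs(corr[i, j]) < 0.1

    def test_matrix_symmetric_with_unit_diagonal(self, scaffold, scaffold_view):
        motion = synthetic.MotionModel(noise=synthetic.NoiseSpec(sigma_A=0.5))
        traj, _ = synthetic.generate_trajectory(scaffold, motion, 30, seed=3)
        corr, _ = rmsd_correlation_matrix(traj, scaffold_view)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        # positive semidefinite within numerical tolerance
        assert np.linalg.eigvalsh(corr).min() > -1e-8


class TestResidueDistanceMap:
    def _system(self):
        return build_system(
            [
                (1, "ALA", [("CA", "C", [0.0, 0.0, 0.0])]),   # target
                (5, "ALA", [("CA", "C", [4.0, 0.0, 0.0])]),
                (9, "ALA", [("CA", "C", [20.0, 0.0, 0.0])]),  # beyond cutoff
            ]
        )

    def test_static_distance_reported(self):
        system = self._system()
        traj = make_trajectory(system, np.stack([system.coordinates()] * 3))
        view = model_io.ProtomerView(system, "A")
        out = residue_distance_map(traj, view, np.array([0]))
        assert out[("A", 5)] == pytest.approx(4.0, abs=1e-9)

    def test_residue_beyond_cutoff_absent(self):
        system = self._system()
        traj = make_trajectory(system, np.stack([system.coordinates()] * 3))
        view = model_io.ProtomerView(system, "A")
        out = residue_distance_map(traj, view, np.array([0]), cutoff_A=10.0)
        assert ("A", 9) not in out

    def test_oscillating_distance_time_averages(self):
        system = self._system()
        base = system.coordinates()
        near, far = base.copy(), base.copy()
        near[1, 0], far[1, 0] = 3.0, 5.0
        traj = make_trajectory(system, np.stack([near, far] * 5))
        view = model_io.ProtomerView(system, "A")
        out = residue_distance_map(traj, view, np.array([0]))
        assert out[("A", 5)] == pytest.approx(4.0, abs=1e-9)


class TestHydrogenBonds:
    def _traj(self, acceptor_pos, h_pos):
        system = build_system(
            [
                (1, "SER", [("OG", "O", [0.0, 0.0, 0.0]),
                            ("HG", "H", h_pos)]),
                (5, "ASP", [("OD1", "O", acceptor_pos)]),
            ]
        )
        return system, make_trajectory(
            system, system.coordinates()[None]
        )

    def test_ideal_linear_bond_counted(self):
        _, traj = self._traj([2.8, 0.0, 0.0], [1.0, 0.0, 0.0])
        out = hydrogen_bonds(traj, donors=[(0, 1)], acceptors=[2])
        assert out["counts"][0] == 1
        assert out["distances_A"][0] == pytest.approx(2.8)

    def test_long_distance_not_counted(self):
        _, traj = self._traj([4.0, 0.0, 0.0], [1.0, 0.0, 0.0])
        out = hydrogen_bonds(traj, donors=[(0, 1)], acceptors=[2])
        assert out["counts"][0] == 0

    def test_bent_geometry_not_counted(self):
        h = [np.cos(np.radians(40)), np.sin(np.radians(40)), 0.0]
        _, traj = self._traj([2.8, 0.0, 0.0], h)
        out = hydrogen_bonds(traj, donors=[(0, 1)], acceptors=[2])
        assert out["counts"][0] == 0

    def test_distance_only_fallback_flagged(self):
        _, traj = self._traj([2.8, 0.0, 0.0], [1.0, 0.0, 0.0])
        out = hydrogen_bonds(traj, donors=[(0, None)], acceptors=[2])
        assert out["counts"][0] == 1
        assert out["distance_only"]

    def test_empty_inputs_warn(self):
        _, traj = self._traj([2.8, 0.0, 0.0], [1.0, 0.0, 0.0])
        with pytest.warns(UserWarning):
            out = hydrogen_bonds(traj, donors=[], acceptors=[])
        assert out["counts"].sum() == 0

    def test_criteria_must_be_positive(self):
        with pytest.raises(ValueError):
            HBondCriteria(donor_acceptor_max_A=-1.0)


class TestDihedrals:
    def _quad_system(self, angle_deg):
        """Four atoms with a prescribed dihedral about the central bond."""
        t = np.radians(angle_deg)
        p0 = [-1.0, 0.0, -1.0]
        p1 = [0.0, 0.0, 0.0]
        p2 = [0.0, 0.0, 1.5]
        p3 = [np.cos(t), np.sin(t), 2.5]
        return build_system(
            [
                (1, "ARG", [
                    ("N", "N", p0), ("CA", "C", p1),
                    ("CB", "C", p2), ("CG", "C", p3),
                ])
            ]
        )

    @pytest.mark.parametrize("angle", [0.0, 60.0, 180.0, -120.0])
    def test_constructed_dihedral_recovered(self, angle):
        system = self._quad_system(angle)
        traj = make_trajectory(system, system.coordinates()[None])
        view = model_io.ProtomerView(system, "A")
        series = dihedral_series(traj, view, 1, "chi1")
        assert series.values_deg[0] == pytest.approx(angle, abs=1e-6)

    def test_chi2_of_serine_is_named_error(self):
        system = build_system(
            [(1, "SER", [("N", "N", [-1, 0, -1]), ("CA", "C", [0, 0, 0]),
                         ("CB", "C", [0, 0, 1.5]), ("OG", "O", [1, 0, 2.5])])]
        )
        traj = make_trajectory(system, system.coordinates()[None])
        view = model_io.ProtomerView(system, "A")
        with pytest.raises(ValueError, match="chi2 undefined.*SER"):
            dihedral_series(traj, view, 1, "chi2")

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 2, (4, 3))
        base = dihedral(*pts)
        rot = random_rotation(rng)
        moved = pts @ rot.T + [5.0, 6.0, 7.0]
        assert dihedral(*moved) == pytest.approx(base, abs=1e-6)


class TestSASA:
    def test_isolated_atom_matches_sphere_area(self):
        area = sasa(np.zeros((1, 3)), ["C"], n_sphere_points=960)
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert area[0] == pytest.approx(expected, rel=0.02)

    def test_fully_overlapping_atoms_count_once(self):
        area = sasa(np.zeros((2, 3)), ["C", "C"], n_sphere_points=960)
        expected = 4 * np.pi * (1.70 + 1.4) ** 2
        assert area.sum() == pytest.approx(expected, rel=0.02)

    def test_caged_atom_is_buried(self):
        # surround one atom with a tight icosahedral-ish cage
        dirs = []
        for sx in (-1, 1):
            for sy in (-1, 1):
                for sz in (-1, 1):
                    dirs.append([sx, sy, sz])
        dirs += [[2, 0, 0], [-2, 0, 0], [0, 2, 0], [0, -2, 0], [0, 0, 2],
                 [0, 0, -2]]
        cage = 1.9 * np.asarray(dirs, dtype=float)
        coords = np.vstack([[0.0, 0.0, 0.0], cage])
        area = sasa(coords, ["C"] * len(coords))
        assert area[0] == pytest.approx(0.0, abs=1e-6)

    def test_unknown_element_listed(self):
        with pytest.raises(ValueError, match="XX"):
            sasa(np.zeros((1, 3)), ["XX"])

    def test_agrees_with_independent_reference(self):
        """Cross-check against biotite's Shrake-Rupley implementation."""
        import biotite.structure as bs

        rng = np.random.default_rng(11)
        pts = rng.normal(0, 3, (25, 3))
        mine = sasa(pts, ["C"] * 25, n_sphere_points=2000)
        arr = bs.AtomArray(25)
        arr.coord = pts.astype(np.float32)
        arr.element = np.array(["C"] * 25)
        arr.atom_name = np.array(["X"] * 25)
        arr.res_id = np.arange(1, 26)
        arr.res_name = np.array(["UNK"] * 25)
        arr.chain_id = np.array(["A"] * 25)
        ref = bs.sasa(
            arr, probe_radius=1.4, point_number=2000,
            vdw_radii=np.full(25, 1.70), ignore_ions=False,
        )
        assert np.abs(mine - ref).max() / ref.max() < 0.02
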