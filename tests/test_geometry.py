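import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from thermotraj import geometry
from thermotraj.geometry import (
    B_FROM_MSF,
    DegenerateSelectionError,
    average_bfactor,
    average_structure,
    bfactor_from_rmsf,
    kabsch_superpose,
    radius_of_gyration,
    rmsd_series,
    rmsf,
)
from thermotraj.io import Trajectory

from .oracles import direct_rgyr, numeric_min_rmsd


class TestKabsch:
    def test_identity_fit(self, rng):
        pts = rng.normal(size=(10, 3))
        fit = kabsch_superpose(pts, pts)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-8)

    def test_rigid_transform_recovered(self, rng):
        pts = rng.normal(size=(8, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([1.0, -2.0, 3.0])
        fit = kabsch_superpose(moved, pts)
        assert fit.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_numeric_orientation_search(self, rng):
        ref = np.array([[0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0, 0, 1.0]], dtype=float)
        mob = ref.copy()
        mob[3] += np.array([1.0, 0, 0])  # one point displaced by 1 A
        mob = mob @ Rotation.random(random_state=7).as_matrix().T + 5.0
        fit = kabsch_superpose(mob, ref)
        oracle = numeric_min_rmsd(mob, ref)
        assert fit.rmsd == pytest.approx(oracle, abs=1e-6)

    def test_degenerate_selections_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateSelectionError):
            kabsch_superpose(line, line)
        two = np.array([[0, 0, 0], [1, 1, 1]], dtype=float)
        with pytest.raises(DegenerateSelectionError):
            kabsch_superpose(two, two)

    def test_rmsd_invariant_under_rigid_transform_of_either_input(self, rng):
        a = rng.normal(size=(12, 3))
        b = a + rng.normal(0, 0.3, size=(12, 3))
        base = kabsch_superpose(a, b).rmsd
        R = Rotation.random(random_state=3).as_matrix()
        assert kabsch_superpose(a @ R.T + 4.0, b).rmsd == pytest.approx(base, abs=1e-9)
        assert kabsch_superpose(a, b @ R.T - 2.0).rmsd == pytest.approx(base, abs=1e-9)


class TestRmsdSeries:
    def test_identical_frames_zero(self, helix12):
        peptide, _ = helix12
        traj = Trajectory(np.repeat(peptide.positions[None], 4, axis=0), 20.0)
        series = rmsd_series(traj, peptide)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_noise_mean_matches_linearized_expectation(self, rng):
        # after a rigid fit the residual loses 6 of the 3N noise dof
        n_atoms, sigma, n_frames = 100, 0.1, 1000
        base = rng.normal(size=(n_atoms, 3)) * 5.0
        coords = base[None] + rng.normal(0, sigma, size=(n_frames, n_atoms, 3))
        traj = Trajectory(coords, 20.0)
        series = rmsd_series(traj, base)
        expected = np.sqrt(3.0) * sigma * np.sqrt((3 * n_atoms - 6) / (3 * n_atoms))
        assert series.mean() == pytest.approx(expected, rel=0.02)

    def test_empty_selection_rejected(self, helix12):
        peptide, _ = helix12
        traj = Trajectory(peptide.positions[None], 20.0)
        with pytest.raises(DegenerateSelectionError):
            rmsd_series(traj, peptide, selection=np.array([], dtype=int))


class TestAverageStructure:
    def test_identical_frames_average_is_frame(self, helix12):
        peptide, _ = helix12
        traj = Trajectory(np.repeat(peptide.positions[None], 5, axis=0), 20.0)
        np.testing.assert_allclose(average_structure(traj), peptide.positions, atol=1e-9)

    def test_mirror_displacement_averages_out(self, helix12):
        peptide, _ = helix12
        base = peptide.positions
        d = np.zeros_like(base)
        d[:, 0] = 0.05  # small so the backbone fit stays essentially identity
        traj = Trajectory(np.stack([base, base + d, base - d]), 20.0)
        avg = average_structure(traj, window=3)
        np.testing.assert_allclose(avg, base, atol=1e-3)

    def test_noise_average_converges_to_reference(self, rng):
        base = rng.normal(size=(50, 3)) * 4.0
        coords = base[None] + rng.normal(0, 0.3, size=(1001, 50, 3))
        coords[0] = base  # clean reference frame
        traj = Trajectory(coords, 20.0)
        errs = []
        for window in (10, 100, 1000):
            avg = average_structure(traj, window=window)
            errs.append(kabsch_superpose(avg, base).rmsd)
        assert errs[0] > errs[1] > errs[2]

    def test_zero_window_rejected(self, helix12):
        peptide, _ = helix12
        traj = Trajectory(np.repeat(peptide.positions[None], 3, axis=0), 20.0)
        with pytest.raises(ValueError):
            average_structure(traj, window=0)


class TestRmsf:
    def test_static_trajectory_zero(self, helix12):
        peptide, _ = helix12
        traj = Trajectory(np.repeat(peptide.positions[None], 10, axis=0), 20.0)
        np.testing.assert_allclose(rmsf(traj), 0.0, atol=1e-9)

    def test_isotropic_noise_closed_form(self, rng):
        # per-coordinate sigma: RMSF -> sqrt(3) sigma
        sigma, n_frames = 0.2, 2000
        base = rng.normal(size=(150, 3)) * 10.0
        coords = base[None] + rng.normal(0, sigma, size=(n_frames, 150, 3))
        traj = Trajectory(coords, 20.0)
        vals = rmsf(traj)
        assert vals.mean() == pytest.approx(np.sqrt(3) * sigma, rel=0.05)

    def test_single_atom_selection_valid(self, rng):
        base = rng.normal(size=(30, 3)) * 5.0
        coords = base[None] + rng.normal(0, 0.1, size=(100, 30, 3))
        traj = Trajectory(coords, 20.0)
        vals = rmsf(traj, selection=np.array([7]), superpose_selection=np.arange(30))
        assert vals.shape == (1,)
        assert vals[0] > 0

    def test_short_window_rejected(self, helix12):
        peptide, _ = helix12
        traj = Trajectory(np.repeat(peptide.positions[None], 5, axis=0), 20.0)
        with pytest.raises(ValueError):
            rmsf(traj, window=1)


class TestBFactor:
    def test_conversion_fixed_points(self, helix12):
        peptide, _ = helix12
        backbone = peptide.backbone_indices()
        # RMSF = sqrt(3/(8 pi^2)) gives B = 1 exactly; RMSF = 1 gives 8 pi^2/3
        inv = np.sqrt(3.0 / (8.0 * np.pi**2))
        prof_zero = bfactor_from_rmsf(np.zeros(backbone.size), peptide, backbone)
        np.testing.assert_allclose(prof_zero.b_values, 0.0)
        prof_inv = bfactor_from_rmsf(np.full(backbone.size, inv), peptide, backbone)
        np.testing.assert_allclose(prof_inv.b_values, 1.0, rtol=1e-12)
        prof_one = bfactor_from_rmsf(np.ones(backbone.size), peptide, backbone)
        np.testing.assert_allclose(prof_one.b_values, 8 * np.pi**2 / 3, rtol=1e-12)

    def test_scaling_quadratic_in_rmsf(self, helix12, rng):
        peptide, _ = helix12
        backbone = peptide.backbone_indices()
        vals = rng.uniform(0.1, 1.0, size=backbone.size)
        b1 = bfactor_from_rmsf(vals, peptide, backbone).b_values
        b3 = bfactor_from_rmsf(3.0 * vals, peptide, backbone).b_values
        np.testing.assert_allclose(b3, 9.0 * b1, rtol=1e-12)

    def test_hydrogens_excluded_from_residue_average(self, helix12):
        peptide, _ = helix12
        all_bb = peptide.backbone_indices(include_hydrogens=True)
        vals = np.ones(all_bb.size)
        # give hydrogens a huge RMSF; residue B must not change
        for k, i in enumerate(all_bb):
            if peptide.atoms[i].is_hydrogen:
                vals[k] = 100.0
        prof = bfactor_from_rmsf(vals, peptide, all_bb)
        np.testing.assert_allclose(prof.b_values, B_FROM_MSF, rtol=1e-12)

    def test_average_bfactor_is_arithmetic_mean(self, helix12, rng):
        peptide, _ = helix12
        backbone = peptide.backbone_indices()
        vals = rng.uniform(0.0, 1.0, size=backbone.size)
        prof = bfactor_from_rmsf(vals, peptide, backbone)
        assert average_bfactor(prof) == pytest.approx(float(np.mean(prof.b_values)))
        with pytest.raises(ValueError):
            average_bfactor(
                geometry.BFactorProfile([], np.array([]), np.array([]), np.array([]))
            )


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3)), np.array([12.0])) == 0.0

    def test_two_equal_masses(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(pts, np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_matches_direct_formula(self, rng):
        pts = rng.normal(size=(100, 3)) * 3.0
        masses = rng.uniform(1.0, 16.0, size=100)
        assert radius_of_gyration(pts, masses) == pytest.approx(
            direct_rgyr(pts, masses), abs=1e-10
        )

    def test_scales_linearly_with_coordinates(self, rng):
        pts = rng.normal(size=(20, 3))
        masses = rng.uniform(1, 10, size=20)
        r1 = radius_of_gyration(pts, masses)
        r2 = radius_of_gyration(2.5 * pts, masses)
        assert r2 == pytest.approx(2.5 * r1, rel=1e-12)


class TestParameterRecovery:
    def test_planted_isotropic_noise_recovers_b(self, rng):
        # expected residue B = 8 pi^2 sigma^2 for per-coordinate sigma
        from thermotraj.synthetic import generate_peptide, generate_trajectory

        sigma = 0.2
        peptide = generate_peptide(30, "extended")
        traj, _ = generate_trajectory(peptide, 2000, noise_sigma=sigma, seed=11, verify=False)
        backbone_heavy = peptide.backbone_indices()
        vals = rmsf(traj, selection=backbone_heavy, superpose_selection=backbone_heavy)
        prof = bfactor_from_rmsf(vals, peptide, backbone_heavy)
        assert float(np.mean(prof.b_values)) == pytest.approx(
            8 * np.pi**2 * sigma**2, rel=0.05
        )
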