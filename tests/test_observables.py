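import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import norm

from ncdsbm import (CaStructure, SimulationParams, TrajectoryEnsemble,
                    residue_distance_series, theta_angle_series,
                    head_stalk_contact_count, contact_formed_mask,
                    pocket_rmsd_series, free_energy_surface,
                    stall_force_estimate, track_axis, pca_modes)
from ncdsbm.observables import FreeEnergySurface
from ncdsbm.synthetic_data import tail_sites
from ncdsbm import constants as C


def static_traj(top, coords_list):
    frames = np.array(coords_list, dtype=float)
    return TrajectoryEnsemble(frames, np.arange(len(frames), dtype=float),
                              SimulationParams(n_steps=0), top,
                              np.arange(top.n_sites), np.zeros((0, 3)))


class TestSeries:
    def test_static_distance_is_constant(self, toy_system):
        top, a, _ = toy_system
        traj = static_traj(top, [a.coords] * 5)
        s = residue_distance_series(traj, ("A", 1), ("A", 40))
        assert np.all(s == s[0])

    def test_oscillating_pair_min_max(self, toy_system):
        top, a, _ = toy_system
        frames = []
        for amp in np.linspace(-1, 1, 21):
            c = a.coords.copy()
            c[-1] = c[0] + [10.0 + amp, 0, 0]
            frames.append(c)
        traj = static_traj(top, frames)
        s = residue_distance_series(traj, ("A", 1), ("A", 40))
        assert s.min() == pytest.approx(9.0)
        assert s.max() == pytest.approx(11.0)

    def test_unknown_residue_raises(self, short_trajectory):
        with pytest.raises(KeyError):
            residue_distance_series(short_trajectory, ("A", 999), ("A", 1))

    def test_theta_collinear_and_right_angle(self, toy_system):
        top, a, _ = toy_system
        c = a.coords.copy()
        c[0] = [0.0, 0, 0]       # apex
        c[1] = [5.0, 0, 0]
        c[2] = [-5.0, 0, 0]
        c[3] = [0.0, 5.0, 0]
        traj = static_traj(top, [c])
        straight = theta_angle_series(traj, ("A", 1), ("A", 2), ("A", 3))
        right = theta_angle_series(traj, ("A", 1), ("A", 2), ("A", 4))
        assert straight[0] == pytest.approx(180.0)
        assert right[0] == pytest.approx(90.0)

    def test_theta_invariant_under_rigid_transform(self, short_trajectory,
                                                   rng):
        traj = short_trajectory
        s0 = theta_angle_series(traj, ("A", 30), ("A", 1), ("A", 40))
        rot = Rotation.random(rng=rng).as_matrix()
        moved = TrajectoryEnsemble(
            traj.frames @ rot.T + np.array([3.0, -8.0, 12.0]), traj.times,
            traj.params, traj.topology, traj.mobile_sites,
            traj.frozen_coords)
        s1 = theta_angle_series(moved, ("A", 30), ("A", 1), ("A", 40))
        np.testing.assert_allclose(s1, s0, atol=1e-9)


class TestContactCounts:
    def test_native_pose_forms_all_dock_contacts_and_no_asymmetric_ones(
            self, toy_spec, toy_system):
        from ncdsbm.synthetic_data import conflicting_dock_masks
        top, a, b = toy_system
        boundary = int(top.residue_ids[tail_sites(toy_spec)[0]])
        counts_a = head_stalk_contact_count(a.coords, top, boundary=boundary,
                                            tolerance=1.1)["A"]
        assert counts_a["S"] > 0
        counts_b = head_stalk_contact_count(b.coords, top, boundary=boundary,
                                            tolerance=1.1)["A"]
        assert counts_b["A"] > counts_a["A"]
        # restricted to genuinely conflicting pairs the split is exact
        s_dock, a_dock = conflicting_dock_masks(top, toy_spec)
        formed_a = contact_formed_mask(a.coords, top, tolerance=1.1)
        formed_b = contact_formed_mask(b.coords, top, tolerance=1.1)
        assert np.all(formed_a[s_dock]) and not np.any(formed_a[a_dock])
        assert np.all(formed_b[a_dock]) and not np.any(formed_b[s_dock])

    def test_dispersed_beads_form_nothing(self, toy_system):
        top, a, _ = toy_system
        far = np.outer(np.arange(top.n_sites), [50.0, 1.0, 0.0])
        assert not contact_formed_mask(far, top).any()

    def test_morph_trades_symmetric_for_asymmetric_contacts(
            self, toy_spec, toy_system):
        """Interpolating dock->flip poses lowers S and raises A counts."""
        top, a, b = toy_system
        boundary = int(top.residue_ids[tail_sites(toy_spec)[0]])
        s_counts, a_counts = [], []
        for t in np.linspace(0, 1, 5):
            c = (1 - t) * a.coords + t * b.coords
            d = head_stalk_contact_count(c, top, boundary=boundary)["A"]
            s_counts.append(d["S"])
            a_counts.append(d["A"])
        assert s_counts[0] == max(s_counts) and s_counts[-1] == min(s_counts)
        assert a_counts[-1] == max(a_counts) and a_counts[0] == min(a_counts)

    def test_tolerance_below_one_rejected(self, toy_system):
        top, a, _ = toy_system
        with pytest.raises(ValueError):
            contact_formed_mask(a.coords, top, tolerance=0.5)


class TestPocketRmsd:
    def test_reference_frame_scores_zero(self, toy_system):
        top, a, _ = toy_system
        traj = static_traj(top, [a.coords])
        pocket = [("A", r) for r in (34, 35, 36)]
        assert pocket_rmsd_series(traj, a, pocket)[0] == pytest.approx(0.0,
                                                                       abs=1e-9)

    def test_rigid_motion_of_whole_chain_is_removed(self, toy_system, rng):
        top, a, _ = toy_system
        rot = Rotation.random(rng=rng).as_matrix()
        moved = a.coords @ rot.T + np.array([4.0, 4.0, -2.0])
        traj = static_traj(top, [moved])
        pocket = [("A", r) for r in (34, 35, 36)]
        assert pocket_rmsd_series(traj, a, pocket)[0] == pytest.approx(0.0,
                                                                       abs=1e-6)

    def test_pure_pocket_displacement_is_measured(self, toy_system):
        top, a, _ = toy_system
        pocket_sites = [33, 34, 35]
        c = a.coords.copy()
        c[pocket_sites] += [1.0, 0, 0]
        traj = static_traj(top, [c])
        pocket = [("A", int(top.residue_ids[i])) for i in pocket_sites]
        head = [("A", int(r)) for r in top.residue_ids[:30]]
        rmsd = pocket_rmsd_series(traj, a, pocket, head=head)[0]
        assert rmsd == pytest.approx(1.0, abs=1e-6)

    def test_missing_pocket_residue_is_error(self, toy_system):
        top, a, _ = toy_system
        traj = static_traj(top, [a.coords])
        with pytest.raises(KeyError):
            pocket_rmsd_series(traj, a, [("A", 500)])


class TestFreeEnergy:
    def test_uniform_samples_are_flat(self):
        u = (np.arange(10_000) + 0.5) / 10_000
        fes = free_energy_surface(u, bins=10)
        assert np.all(np.isfinite(fes.free_energy))
        assert fes.free_energy.max() < 0.01

    def test_two_state_gap(self):
        series = np.concatenate([np.zeros(880), np.ones(120)])
        fes = free_energy_surface(series, bins=2)
        gap = fes.free_energy.max()
        assert gap == pytest.approx(np.log(0.88 / 0.12), abs=1e-12)

    def test_gaussian_curvature(self):
        sigma = 2.0
        u = (np.arange(1, 20_000) / 20_000)
        samples = sigma * norm.ppf(u)
        fes = free_energy_surface(samples, bins=25)
        z = fes.bin_centers()
        keep = np.isfinite(fes.free_energy) & (np.abs(z) < 2 * sigma)
        coeffs = np.polyfit(z[keep], fes.free_energy[keep], 2)
        assert coeffs[0] == pytest.approx(1 / (2 * sigma ** 2), rel=0.05)

    def test_reexponentiation_recovers_histogram(self, rng):
        samples = rng.standard_normal(3000)
        fes = free_energy_surface(samples, bins=15)
        recon = fes.probabilities() * fes.n_frames
        np.testing.assert_allclose(recon[fes.counts > 0],
                                   fes.counts[fes.counts > 0], rtol=1e-9)
        assert fes.counts.sum() == fes.n_frames

    def test_single_bin_and_empty_series(self):
        fes = free_energy_surface(np.full(10, 3.3), bins=1)
        assert fes.free_energy[0] == 0.0
        with pytest.raises(ValueError):
            free_energy_surface(np.zeros(0))

    def test_2d_surface(self, rng):
        a = rng.standard_normal(5000)
        b = rng.standard_normal(5000)
        fes = free_energy_surface((a, b), bins=20)
        assert fes.free_energy.shape == (20, 20)
        assert fes.free_energy[np.isfinite(fes.free_energy)].min() == 0.0


class TestStallForce:
    def linear_fes(self, slope_kt_per_ang, zmax=50.0, nbins=26):
        edges = np.linspace(0, zmax, nbins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        f = slope_kt_per_ang * centers
        p = np.exp(-f)
        counts = np.round(1e6 * p / p.sum()).astype(np.int64)
        return FreeEnergySurface([edges], f - f.min(), counts,
                                 int(counts.sum()))

    def test_unit_conversion(self):
        fes = self.linear_fes(0.1)   # 1 k_BT per 10 Å
        pn = stall_force_estimate(fes, temperature=300.0)
        assert pn == pytest.approx(0.1 * C.KB * 300 *
                                   C.KCAL_PER_MOL_ANG_IN_PN)
        assert pn == pytest.approx(4.142, abs=0.001)

    def test_flat_profile_gives_zero(self):
        fes = self.linear_fes(0.0)
        assert stall_force_estimate(fes) == 0.0

    def test_scales_linearly_with_temperature(self):
        fes = self.linear_fes(0.2)
        f300 = stall_force_estimate(fes, temperature=300.0)
        f600 = stall_force_estimate(fes, temperature=600.0)
        assert f600 == pytest.approx(2 * f300)

    def test_endpoint_variant_and_errors(self):
        fes = self.linear_fes(0.1)
        assert stall_force_estimate(fes, method="endpoint") == \
            pytest.approx(stall_force_estimate(fes), rel=1e-9)
        with pytest.raises(ValueError):
            stall_force_estimate(fes, method="nope")
        tiny = FreeEnergySurface([np.array([0.0, 1.0])], np.array([0.0]),
                                 np.array([5]), 5)
        with pytest.raises(ValueError):
            stall_force_estimate(tiny)

    def test_track_axis_of_lattice(self):
        from ncdsbm import generate_track, TrackSpec
        track = generate_track(TrackSpec(n_x=12, n_z=3))
        axis = track_axis(track.coords)
        assert abs(axis[0]) == pytest.approx(1.0, abs=1e-9)


class TestPCA:
    def test_identical_frames_have_zero_eigenvalues(self, toy_system):
        top, a, _ = toy_system
        traj = static_traj(top, [a.coords] * 6)
        res = pca_modes(traj, a, n_modes=2)
        assert np.all(res.eigenvalues < 1e-18)

    def test_single_frame_is_error(self, toy_system):
        top, a, _ = toy_system
        traj = static_traj(top, [a.coords])
        with pytest.raises(ValueError):
            pca_modes(traj, a)

    def test_mode_export_as_multi_model_pdb(self, short_trajectory,
                                            toy_system):
        top, a, _ = toy_system
        res = pca_modes(short_trajectory, a, n_modes=2)
        text = res.to_multi_model_pdb(top, mode=0, n_models=5)
        assert text.count("MODEL") == 5
        from ncdsbm import read_ca_structure
        first = text.split("ENDMDL")[0]
        body = "\n".join(ln for ln in first.splitlines()
                         if not ln.startswith("MODEL"))
        s = read_ca_structure(body + "\nEND\n")
        assert s.n_sites == top.n_sites

    def test_orthonormal_modes_and_trace_identity(self, short_trajectory,
                                                  toy_system):
        _, a, _ = toy_system
        res = pca_modes(short_trajectory, a, n_modes=4)
        g = res.modes.reshape(4, -1) @ res.modes.reshape(4, -1).T
        np.testing.assert_allclose(g, np.eye(4), atol=1e-8)
        assert res.eigenvalues.min() >= 0.0
        # eigenvalue sum equals total superposed variance
        traj = short_trajectory
        from ncdsbm.structure_io import superpose
        top = traj.topology
        sites = np.arange(top.n_sites)
        pairs = np.column_stack([sites, sites])
        fitted = []
        ref = a
        for f in range(traj.n_frames):
            s = CaStructure(top.residue_ids, top.chain_ids,
                            top.residue_names, traj.full_coords(f))
            rot, t, _ = superpose(s, ref, pairs)
            fitted.append(s.coords @ rot.T + t)
        fitted = np.array(fitted)
        disp = fitted - fitted.mean(axis=0)
        trace = float(np.sum(disp ** 2) / traj.n_frames)
        assert res.eigenvalues.sum() == pytest.approx(trace, rel=1e-6)
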