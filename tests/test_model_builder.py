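import numpy as np
import pytest

from ncdsbm import (CaStructure, compute_contact_map,
                    build_dual_basin_topology, assign_epsilons,
                    build_mt_bound_complex, delete_junction_contacts,
                    DualBasinTopology, apply_transform,
                    generate_two_conformer_chain, generate_track,
                    ToyDualBasinSpec, TrackSpec)
from ncdsbm.model_builder import BASIN_S, BASIN_A
from ncdsbm.synthetic_data import tail_sites
from scipy.spatial.transform import Rotation


def chain(coords, start_id=1, chain_id="A"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return CaStructure(np.arange(start_id, start_id + n), [chain_id] * n,
                       ["GLY"] * n, coords)


class TestContactMap:
    def test_straight_chain_has_no_contacts(self):
        s = chain(np.outer(np.arange(6), [3.8, 0, 0]))
        assert compute_contact_map(s) == []

    def test_hairpin_contact_present(self):
        coords = np.zeros((8, 3))
        coords[:, 0] = np.arange(8) * 3.8
        coords[7] = [0.0, 6.0, 0.0]   # residue 8 folded back over residue 1
        s = chain(coords)
        found = {(i, j): d for i, j, d in compute_contact_map(s)}
        assert (0, 7) in found
        assert found[(0, 7)] == pytest.approx(6.0)

    def test_matches_brute_force(self, rng):
        coords = 12.0 * rng.standard_normal((30, 3))
        s = chain(coords)
        got = {(i, j) for i, j, _ in compute_contact_map(s)}
        expected = set()
        for i in range(30):
            for j in range(i + 1, 30):
                if j - i > 3 and np.linalg.norm(coords[i] - coords[j]) < 8.0:
                    expected.add((i, j))
        assert got == expected

    def test_interchain_pairs_ignore_separation(self):
        a = np.outer(np.arange(5), [3.8, 0, 0])
        b = a + [0, 5.0, 0]
        s = CaStructure(np.tile(np.arange(1, 6), 2),
                        ["A"] * 5 + ["B"] * 5, ["GLY"] * 10, np.vstack([a, b]))
        got = {(i, j) for i, j, _ in compute_contact_map(s)}
        assert (0, 5) in got      # same residue number, different chains

    def test_empty_structure_is_error(self):
        with pytest.raises(ValueError):
            compute_contact_map(chain(np.zeros((0, 3))))


class TestDualBasinTopology:
    def test_identical_conformers_collapse_to_single_basin(self, toy_spec):
        a, _, m = generate_two_conformer_chain(toy_spec)
        top = build_dual_basin_topology(a, a, m, neck_threshold=None)
        assert int((top.contact_basin == BASIN_A).sum()) == 0
        top.validate()

    def test_tail_swing_contacts_are_exactly_the_new_docking_patch(
            self, toy_spec, toy_system):
        top, a, b = toy_system
        tails = set(tail_sites(toy_spec).tolist())
        a_pairs = top.contact_pairs[top.contact_basin == BASIN_A]
        assert len(a_pairs) > 0
        # every asymmetric-only contact involves the re-docked tail
        assert all((i in tails) or (j in tails) for i, j in a_pairs)
        # and equals the brute-force set difference of the two maps
        s_map = {(i, j) for i, j, _ in compute_contact_map(a)}
        b_map = {(i, j) for i, j, _ in compute_contact_map(b)}
        assert {tuple(p) for p in a_pairs} == b_map - s_map

    def test_basins_are_disjoint_and_native_values_from_symmetric(
            self, toy_system):
        top, a, _ = toy_system
        s_set = {tuple(p) for p in top.contact_pairs[top.contact_basin == BASIN_S]}
        a_set = {tuple(p) for p in top.contact_pairs[top.contact_basin == BASIN_A]}
        assert not (s_set & a_set)
        # bond native lengths come from conformer A
        np.testing.assert_allclose(
            top.bond_r0,
            np.linalg.norm(a.coords[top.bonds[:, 1]]
                           - a.coords[top.bonds[:, 0]], axis=1))
        # S-contact equilibrium distances come from conformer A
        for (i, j), r0, bas in zip(top.contact_pairs, top.contact_r0,
                                   top.contact_basin):
            if bas == BASIN_S and i < 40 and j < 40:
                assert r0 == pytest.approx(
                    np.linalg.norm(a.coords[i] - a.coords[j]), abs=1e-9)

    def test_site_map_gap_reports_residues(self, toy_spec):
        a, b, _ = generate_two_conformer_chain(toy_spec)
        partial = np.column_stack([np.arange(10), np.arange(10)])
        with pytest.raises(ValueError, match="A:11"):
            build_dual_basin_topology(a, b, partial)

    def test_serialization_roundtrip_is_exact(self, toy_system):
        top, _, _ = toy_system
        back = DualBasinTopology.from_json(top.to_json())
        np.testing.assert_array_equal(back.contact_pairs, top.contact_pairs)
        np.testing.assert_array_equal(back.contact_basin, top.contact_basin)
        np.testing.assert_array_equal(back.contact_r0, top.contact_r0)
        np.testing.assert_array_equal(back.dihedral_phi0, top.dihedral_phi0)
        np.testing.assert_array_equal(back.frozen_sites, top.frozen_sites)
        assert back.repulsion_sigma == top.repulsion_sigma


class TestEpsilons:
    def build(self, pairs, ids):
        n = max(max(p) for p in pairs) + 1
        rid = np.array(ids)
        return DualBasinTopology(
            rid, ["A"] * n, ["GLY"] * n, np.zeros((n, 3)),
            np.zeros((0, 2)), np.zeros(0), np.zeros((0, 3)), np.zeros(0),
            np.zeros((0, 4)), np.zeros(0),
            np.array(pairs), np.array(["S", "S", "IF"]),
            np.full(len(pairs), 5.0), np.ones(len(pairs)))

    def test_neck_interface_and_generic_depths(self):
        # sites carry author numbers 300, 320, 400, 567, 450 (+ a track bead)
        top = DualBasinTopology(
            [300, 320, 400, 567, 450, 1], ["A"] * 5 + ["T"],
            ["GLY"] * 6, np.zeros((6, 3)),
            np.zeros((0, 2)), np.zeros(0), np.zeros((0, 3)), np.zeros(0),
            np.zeros((0, 4)), np.zeros(0),
            [[0, 1], [2, 3], [4, 5]], ["S", "S", "IF"],
            [5.0, 5.0, 5.0], [1.0, 1.0, 1.0])
        out = assign_epsilons(top, neck_threshold=331)
        eps = dict(zip(map(tuple, out.contact_pairs.tolist()), out.contact_eps))
        assert eps[(0, 1)] == 1.8      # both < 331: upper neck
        assert eps[(2, 3)] == 1.0      # head-head
        assert eps[(4, 5)] == 1.8      # motor-track interface

    def test_asymmetric_depth_knob(self, toy_spec):
        a, b, m = generate_two_conformer_chain(toy_spec)
        top = build_dual_basin_topology(a, b, m, neck_threshold=None,
                                        epsilon_asymmetric=1.7)
        assert np.all(top.contact_eps[top.contact_basin == BASIN_A] == 1.7)
        assert np.all(top.contact_eps[top.contact_basin == BASIN_S] == 1.0)


class TestTrackComplex:
    def test_identity_placement_preserves_coordinates(self, toy_spec):
        a, _, _ = generate_two_conformer_chain(toy_spec)
        track = generate_track(TrackSpec(), x_center=float(a.coords[:, 0].mean()))
        merged, interface = build_mt_bound_complex(a, track, truncate_track=None)
        np.testing.assert_allclose(merged.coords[:a.n_sites], a.coords,
                                   atol=1e-6)
        assert len(interface) >= 5

    def test_interface_equals_brute_force_scan(self, toy_spec):
        a, _, _ = generate_two_conformer_chain(toy_spec)
        track = generate_track(TrackSpec(), x_center=float(a.coords[:, 0].mean()))
        merged, interface = build_mt_bound_complex(a, track, truncate_track=None)
        n = a.n_sites
        expected = set()
        for i in range(n):
            for j in range(track.n_sites):
                if np.linalg.norm(a.coords[i] - track.coords[j]) < 8.0:
                    expected.add((i, n + j))
        assert {(i, j) for i, j, _ in interface} == expected

    def test_adaptor_chained_superposition_recovers_pose(self, toy_spec, rng):
        """A binder scrambled by a rigid transform is put back onto the
        track via an adaptor that shows the correct pose."""
        a, _, _ = generate_two_conformer_chain(toy_spec)
        track = generate_track(TrackSpec(), x_center=float(a.coords[:, 0].mean()))
        adaptor = a.copy()          # homolog already posed on this track
        rot = Rotation.random(rng=rng).as_matrix()
        scrambled = apply_transform(a, rot, np.array([30.0, -12.0, 7.0]))
        pairs = np.column_stack([np.arange(a.n_sites), np.arange(a.n_sites)])
        track_pairs = np.column_stack([np.arange(track.n_sites),
                                       np.arange(track.n_sites)])
        # the adaptor complex pairs onto the lattice by identity here; the
        # scrambled binder is then carried onto the adaptor's pose
        adaptor_track = adaptor  # toy stand-in: pose reference == binder pose
        merged, _ = build_mt_bound_complex(
            scrambled, adaptor_track, adaptor=adaptor,
            binder_to_adaptor_pairs=pairs,
            adaptor_to_track_pairs=pairs, truncate_track=None)
        np.testing.assert_allclose(merged.coords[:a.n_sites], a.coords,
                                   atol=1e-6)
        with pytest.raises(ValueError, match="both pairings"):
            build_mt_bound_complex(scrambled, track, adaptor=adaptor,
                                   binder_to_adaptor_pairs=pairs)

    def test_track_truncation_drops_distant_beads(self, toy_spec):
        a, _, _ = generate_two_conformer_chain(toy_spec)
        track = generate_track(TrackSpec(n_x=40), x_center=200.0)
        merged, interface = build_mt_bound_complex(a, track,
                                                   truncate_track=40.0)
        assert merged.n_sites < a.n_sites + track.n_sites
        assert interface == []


class TestJunctionDeletion:
    def test_no_matching_contacts_warns_not_raises(self, toy_system, caplog):
        top, _, _ = toy_system
        out, count = delete_junction_contacts(top, (900, 905), (910, 915))
        assert count == 0
        assert len(out.contact_pairs) == len(top.contact_pairs)

    def test_constructed_spanning_contacts_are_removed(self):
        rid = np.arange(340, 356)
        n = len(rid)
        pairs = [[1, 7], [2, 8], [3, 9], [5, 11], [0, 14], [12, 15]]
        basins = ["S", "S", "S", "S", "S", "A"]
        top = DualBasinTopology(
            rid, ["A"] * n, ["GLY"] * n, np.zeros((n, 3)),
            np.zeros((0, 2)), np.zeros(0), np.zeros((0, 3)), np.zeros(0),
            np.zeros((0, 4)), np.zeros(0),
            pairs, basins, np.full(6, 5.0), np.ones(6))
        # stalk 341-345 = sites 1..5, head 346-351 = sites 6..11
        out, count = delete_junction_contacts(top, (341, 345), (346, 351))
        assert count == 4
        kept = {tuple(p) for p in out.contact_pairs.tolist()}
        assert kept == {(0, 14), (12, 15)}

    def test_matches_brute_force_filter_and_is_idempotent(self, toy_system):
        top, _, _ = toy_system
        stalk, head = (5, 9), (20, 30)
        rid = top.residue_ids

        def spans(p):
            ri, rj = rid[p[0]], rid[p[1]]
            return ((stalk[0] <= ri <= stalk[1] and head[0] <= rj <= head[1])
                    or (stalk[0] <= rj <= stalk[1] and head[0] <= ri <= head[1]))

        expected = {tuple(p) for p, bas in
                    zip(top.contact_pairs.tolist(), top.contact_basin)
                    if bas == BASIN_S and spans(p)}
        out, count = delete_junction_contacts(top, stalk, head)
        assert count == len(expected) > 0
        assert not ({tuple(p) for p in out.contact_pairs.tolist()} & expected)
        out2, count2 = delete_junction_contacts(out, stalk, head)
        assert count2 == 0
        assert len(out2.contact_pairs) == len(out.contact_pairs)
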