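"""Spring selection, deformation energies and Monte Carlo probe docking."""

import numpy as np
import pytest

from allokit.leverage import (ProbePose, SpringSet, binding_leverage_score,
                              cluster_poses, mc_dock_probe, mode_delta_u,
                              per_residue_leverage, rank_candidate_sites,
                              select_springs, site_from_pose)


def brute_force_springs(ca, probe, shell):
    """Point-to-segment scan over all pairs, no prefilter (oracle)."""
    pairs = set()
    probe = np.asarray(probe, float).reshape(-1, 3)
    for i in range(len(ca)):
        for j in range(i + 1, len(ca)):
            a, b = ca[i], ca[j]
            ab = b - a
            for p in probe:
                t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
                if np.linalg.norm(p - (a + t * ab)) <= shell:
                    pairs.add((i, j))
                    break
    return pairs


def one_spring(d=10.0):
    return SpringSet(pairs=np.array([[0, 1]]), rest_lengths=np.array([d]),
                     unit_vectors=np.array([[1.0, 0.0, 0.0]]), kappa=1.0)


class TestSelectSprings:
    def test_probe_on_segment_midpoint_selected(self):
        ca = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        springs = select_springs(ca, np.array([[5.0, 0, 0]]))
        assert len(springs) == 1

    def test_probe_five_angstrom_off_not_selected(self):
        ca = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        springs = select_springs(ca, np.array([[5.0, 5.0, 0]]))
        assert len(springs) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_and_prefilter_safe(self, seed):
        rng = np.random.default_rng(seed)
        ca = rng.uniform(-30, 30, (25, 3))
        probe = rng.uniform(-10, 10, (4, 3))
        got = {tuple(p) for p in select_springs(ca, probe).pairs}
        unfiltered = {tuple(p) for p in
                      select_springs(ca, probe, prefilter=None).pairs}
        assert got == unfiltered == brute_force_springs(ca, probe, 3.5)

    def test_probe_order_invariance(self):
        rng = np.random.default_rng(3)
        ca = rng.uniform(-15, 15, (12, 3))
        probe = rng.uniform(-5, 5, (5, 3))
        a = select_springs(ca, probe).pairs
        b = select_springs(ca, probe[::-1]).pairs
        assert {tuple(p) for p in a} == {tuple(p) for p in b}

    def test_rest_lengths_and_units(self):
        ca = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        springs = select_springs(ca, np.array([[5.0, 0, 0]]))
        assert springs.rest_lengths[0] == pytest.approx(10.0)
        np.testing.assert_allclose(np.abs(springs.unit_vectors[0]),
                                   [1, 0, 0])


class TestModeDeltaU:
    def test_hand_computed_single_spring(self):
        # relative displacement 2 along the spring axis: dU = (k/2)*2^2
        mode = np.array([1.0, 0, 0, -1.0, 0, 0])
        assert mode_delta_u(one_spring(), mode) == pytest.approx(2.0)

    def test_pure_translation_costs_nothing(self):
        mode = np.array([1.0, 0, 0, 1.0, 0, 0])
        assert mode_delta_u(one_spring(), mode) == 0.0

    def test_kappa_and_amplitude_scaling(self):
        mode = np.array([1.0, 0, 0, -1.0, 0, 0])
        s2 = one_spring()
        s2.kappa = 3.0
        assert mode_delta_u(s2, mode) == pytest.approx(6.0)
        assert mode_delta_u(one_spring(), 2 * mode) == pytest.approx(8.0)

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            mode_delta_u(one_spring(), np.zeros(3))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_linearization_matches_finite_difference(self, seed):
        rng = np.random.default_rng(seed)
        ca = rng.uniform(-10, 10, (8, 3))
        probe = ca.mean(axis=0, keepdims=True) + rng.normal(0, 2, (2, 3))
        springs = select_springs(ca, probe, shell=6.0)
        assert len(springs) > 0
        u = rng.normal(size=(8, 3))
        du = mode_delta_u(springs, u.ravel())

        def exact(eps):
            moved = ca + eps * u
            e = 0.0
            for (i, j), d0 in zip(springs.pairs, springs.rest_lengths):
                e += 0.5 * (np.linalg.norm(moved[i] - moved[j]) - d0) ** 2
            return e

        ratios = [exact(eps) / eps**2 / du for eps in (1e-3, 1e-4)]
        assert ratios[1] == pytest.approx(1.0, abs=1e-3)
        assert abs(ratios[1] - 1) < abs(ratios[0] - 1) + 1e-9

    def test_rigid_displacement_of_whole_system(self, blob, blob_modes):
        ca = blob.ca_coords()
        springs = select_springs(ca, ca.mean(axis=0, keepdims=True),
                                 shell=6.0)
        # synthetic rigid rotation displacement field
        omega = np.array([0.3, -0.2, 0.5])
        disp = np.cross(np.broadcast_to(omega, ca.shape),
                        ca - ca.mean(axis=0))
        assert mode_delta_u(springs, disp.ravel()) == pytest.approx(
            0.0, abs=1e-10 * np.abs(disp).max()**2 * len(springs))


class TestBindingLeverageScore:
    def test_single_mode_subset(self, blob, blob_modes):
        ca = blob.ca_coords()
        springs = select_springs(ca, ca.mean(axis=0, keepdims=True), 5.0)
        one = binding_leverage_score(springs, blob_modes, [2])
        assert one.total == pytest.approx(
            mode_delta_u(springs, blob_modes.eigenvectors[:, 2]))

    def test_empty_springs_zero_total(self, blob_modes):
        empty = SpringSet(pairs=np.empty((0, 2), int),
                          rest_lengths=np.empty(0),
                          unit_vectors=np.empty((0, 3)))
        assert binding_leverage_score(empty, blob_modes).total == 0.0

    def test_additivity_over_modes(self, blob, blob_modes):
        ca = blob.ca_coords()
        springs = select_springs(ca, ca.mean(axis=0, keepdims=True), 5.0)
        total = binding_leverage_score(springs, blob_modes).total
        parts = sum(binding_leverage_score(springs, blob_modes, [m]).total
                    for m in range(blob_modes.n_modes))
        assert total == pytest.approx(parts)

    def test_empty_subset_errors(self, blob, blob_modes):
        springs = select_springs(blob.ca_coords(),
                                 blob.ca_coords()[:1], 5.0)
        with pytest.raises(ValueError):
            binding_leverage_score(springs, blob_modes, [])


class TestMcDockProbe:
    @pytest.mark.parametrize("size", [1, 7])
    def test_probe_size_out_of_range(self, pocket, size):
        with pytest.raises(ValueError, match="2 and 6"):
            mc_dock_probe(pocket, probe_size=size)

    def test_same_seed_is_bit_identical(self, pocket):
        a = mc_dock_probe(pocket, 4, n_runs=3, n_steps=300, seed=11)
        b = mc_dock_probe(pocket, 4, n_runs=3, n_steps=300, seed=11)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.beads, pb.beads)
            assert pa.energy == pb.energy and pa.step == pb.step

    def test_bead_spacing_preserved(self, pocket):
        poses = mc_dock_probe(pocket, 5, n_runs=2, n_steps=500, seed=2)
        for p in poses:
            d = np.linalg.norm(np.diff(p.beads, axis=0), axis=1)
            np.testing.assert_allclose(d, 3.8, atol=1e-6)

    def test_pocket_recall_beats_surface_placement(self, pocket):
        """The cavity attracts docked probes far more often than any
        equally sized neighborhood of a reference point on the outer
        wall."""
        center = np.array(pocket.metadata["pocket_center"])
        atoms, _ = pocket.heavy_atom_table()
        surface_ref = np.array([atoms[:, 0].max() + 5.0, 0.0, 0.0])
        poses = mc_dock_probe(pocket, 4, n_runs=20, n_steps=10000, seed=0)
        pocket_hits = sum(
            float(np.linalg.norm(p.beads - center, axis=1).max()) < 8.0
            for p in poses)
        surface_hits = sum(
            float(np.linalg.norm(p.beads - surface_ref, axis=1).max()) < 8.0
            for p in poses)
        assert pocket_hits > surface_hits


def pose(beads, energy, run_id=0):
    return ProbePose(beads=np.asarray(beads, float), energy=energy,
                     run_id=run_id, step=0)


class TestRankCandidateSites:
    def test_identical_poses_form_one_cluster(self):
        b = [[0, 0, 0], [3.8, 0, 0]]
        assert len(cluster_poses([pose(b, -5), pose(b, -4, 1)])) == 1

    def test_distant_poses_form_two_clusters(self):
        b1 = [[0, 0, 0], [3.8, 0, 0]]
        b2 = [[50, 0, 0], [53.8, 0, 0]]
        assert len(cluster_poses([pose(b1, -5), pose(b2, -4, 1)])) == 2

    def test_ranked_by_leverage_descending(self, hinge, hinge_modes):
        cleft = np.array(hinge.metadata["cleft_center"])
        far = hinge.ca_coords()[0] + np.array([0, 0, 8.0])
        poses = [pose(cleft + [[-1.9, 0, 0], [1.9, 0, 0]], -30),
                 pose([far, far + [3.8, 0, 0]], -20, 1)]
        ranked = rank_candidate_sites(hinge, poses, hinge_modes)
        totals = [res.total for _, res in ranked]
        assert totals == sorted(totals, reverse=True)

    def test_cleft_pose_outleverages_surface_pose(self, hinge, hinge_modes):
        ca = hinge.ca_coords()
        cleft = np.array(hinge.metadata["cleft_center"])
        sl1 = slice(*hinge.metadata["cluster1"])
        far_idx = int(np.argmax(np.linalg.norm(ca[sl1] - cleft, axis=1)))
        out = ca[far_idx] - ca[sl1].mean(axis=0)
        out /= np.linalg.norm(out)
        offsets = np.array([[-1.9, 0, 0], [1.9, 0, 0],
                            [-1.9, 3.8, 0], [1.9, 3.8, 0]])
        from allokit.leverage import binding_leverage_score, select_springs
        l_cleft = binding_leverage_score(
            select_springs(ca, cleft + offsets), hinge_modes).total
        l_surf = binding_leverage_score(
            select_springs(ca, ca[far_idx] + 3.0 * out + offsets),
            hinge_modes).total
        assert l_cleft > l_surf


class TestPerResidueLeverage:
    def test_single_pose_site_shares_value(self, blob, blob_modes):
        beads = blob.ca_coords().mean(axis=0, keepdims=True).repeat(2, 0)
        beads[1] += [3.8, 0, 0]
        p = pose(beads, -10)
        values = per_residue_leverage(blob, [p], blob_modes)
        site = site_from_pose(blob, beads, "x")
        inside = {values[k] for k in site.residue_keys}
        assert len(inside) == 1
        assert all(values[r.key] == 0.0 for r in blob.residues
                   if r.key not in site.residue_keys)

    def test_no_poses_all_zero(self, blob, blob_modes):
        values = per_residue_leverage(blob, [], blob_modes)
        assert set(values.values()) == {0.0}

    def test_overlapping_poses_take_max(self, blob, blob_modes):
        rng = np.random.default_rng(8)
        center = blob.ca_coords().mean(axis=0)
        poses = []
        for k in range(3):
            start = center + rng.normal(0, 2, 3)
            poses.append(pose([start, start + [3.8, 0, 0]], -5.0, k))
        values = per_residue_leverage(blob, poses, blob_modes)
        from allokit.leverage import binding_leverage_score, select_springs
        ca = blob.ca_coords()
        for r in blob.residues:
            best = 0.0
            for p in poses:
                site = site_from_pose(blob, p.beads, "x")
                if r.key in site.residue_keys:
                    tot = binding_leverage_score(
                        select_springs(ca, p.beads), blob_modes).total
                    best = max(best, tot)
            assert values[r.key] == pytest.approx(best)
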