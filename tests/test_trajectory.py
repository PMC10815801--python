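"""Trajectory analytics: Kabsch superposition, GROMOS clustering, hbonds."""

import numpy as np
import pandas as pd
import pytest

from aptapanel.simulate import TrajectorySimConfig, gen_trajectory
from aptapanel.trajectory import (
    ClusterResult,
    HBondSpec,
    Trajectory,
    gromos_cluster,
    hbond_occupancy,
    kabsch_superpose,
    pairwise_rmsd_matrix,
    rmsd_series,
    superposed_rmsd,
)
from aptapanel import traj_io


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    a = np.cos(angle / 2)
    b, c, d = -axis * np.sin(angle / 2)
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c + a * d), 2 * (b * d - a * c)],
            [2 * (b * c - a * d), a * a + c * c - b * b - d * d, 2 * (c * d + a * b)],
            [2 * (b * d + a * c), 2 * (c * d - a * b), a * a + d * d - b * b - c * c],
        ]
    )


def make_traj(coords, boundaries=()):
    coords = np.asarray(coords, float)
    labels = [f"CA:{i + 1}" for i in range(coords.shape[1])]
    return Trajectory(coords=coords, labels=labels, replicate_boundaries=boundaries)


class TestKabsch:
    def test_identical_sets(self, rng):
        P = rng.normal(size=(6, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)

    def test_rigid_transform_recovered(self, rng):
        P = rng.normal(size=(8, 3))
        R_true = rotation_matrix([1, 2, 3], 1.1)
        Q = P @ R_true.T + np.array([4.0, -2.0, 7.0])
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(Q @ R.T + t, P, atol=1e-9)

    def test_symmetry(self, rng):
        P, Q = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert superposed_rmsd(P, Q) == pytest.approx(superposed_rmsd(Q, P), abs=1e-10)

    def test_superposed_rmsd_never_exceeds_raw(self, rng):
        for _ in range(20):
            P, Q = rng.normal(size=(7, 3)), rng.normal(size=(7, 3))
            raw = np.sqrt(((P - Q) ** 2).sum(axis=1).mean())
            assert superposed_rmsd(P, Q) <= raw + 1e-10

    def test_rotation_grid_oracle(self, rng):
        """The Kabsch optimum beats a fine grid over rotations for 4-point sets."""
        P = rng.normal(size=(4, 3))
        Q = rng.normal(size=(4, 3))
        best = kabsch_superpose(P, Q)[2]
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        angles = np.linspace(0, 2 * np.pi, 25, endpoint=False)
        grid_best = np.inf
        for ax in ([1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1]):
            for a1 in angles:
                for a2 in angles:
                    R = rotation_matrix(ax, a1) @ rotation_matrix([0, 0, 1], a2)
                    d = Qc @ R.T - Pc
                    grid_best = min(grid_best, np.sqrt((d * d).sum() / 4))
        assert best <= grid_best + 1e-9
        assert best == pytest.approx(grid_best, abs=0.2)  # grid resolution tolerance

    def test_agrees_with_mdanalysis(self, rng):
        """Cross-check the superposed RMSD against an independent library."""
        mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
        for _ in range(10):
            P, Q = rng.normal(size=(9, 3)), rng.normal(size=(9, 3))
            expected = mda_rms.rmsd(Q, P, center=True, superposition=True)
            assert superposed_rmsd(P, Q) == pytest.approx(expected, abs=1e-8)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="3 atoms"):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_constant_trajectory_is_zero(self, rng):
        frame = rng.normal(size=(5, 3))
        traj = make_traj(np.repeat(frame[None], 4, axis=0))
        series = rmsd_series(traj)
        np.testing.assert_allclose(series["rmsd"], 0.0, atol=1e-10)

    def test_single_frame(self, rng):
        traj = make_traj(rng.normal(size=(1, 4, 3)))
        np.testing.assert_allclose(rmsd_series(traj)["rmsd"], [0.0], atol=1e-12)

    def test_reference_out_of_range(self, rng):
        traj = make_traj(rng.normal(size=(2, 4, 3)))
        with pytest.raises(IndexError):
            rmsd_series(traj, reference=5)

    def test_replicate_column_honors_boundaries(self, rng):
        traj = make_traj(rng.normal(size=(6, 4, 3)), boundaries=(2, 4))
        series = rmsd_series(traj)
        assert list(series["replicate"]) == [0, 0, 1, 1, 2, 2]

    def test_two_cluster_trajectory_is_bimodal(self):
        traj, truth = gen_trajectory(TrajectorySimConfig(
            n_frames_per_replicate=20, n_replicates=1, n_centers=2, seed=2
        ))
        series = rmsd_series(traj, reference=0)
        own = series["rmsd"][truth.cluster_of_frame == truth.cluster_of_frame[0]]
        other = series["rmsd"][truth.cluster_of_frame != truth.cluster_of_frame[0]]
        assert own.max() < 1.0 < 2.5 < other.min()


def brute_force_gromos(m: np.ndarray, cutoff: float) -> np.ndarray:
    """Independent reference implementation by explicit neighbor counting."""
    n = m.shape[0]
    unassigned = set(range(n))
    raw = []
    while unassigned:
        best, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned if m[i, j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = sorted(j for j in unassigned if m[best, j] <= cutoff)
        raw.append(members)
        unassigned -= set(members)
    raw.sort(key=lambda members: -len(members))
    assignment = np.empty(n, dtype=int)
    for k, members in enumerate(raw):
        for j in members:
            assignment[j] = k
    return assignment


def partitions_equal(a, b) -> bool:
    """Same grouping of frames, up to cluster relabelling."""
    pairs = set(zip(a.tolist(), b.tolist()))
    return len(pairs) == len(set(a.tolist())) == len(set(b.tolist()))


class TestGromosCluster:
    def test_all_identical_frames_form_one_cluster(self, rng):
        frame = rng.normal(size=(4, 3))
        traj = make_traj(np.repeat(frame[None], 5, axis=0))
        result = gromos_cluster(traj, cutoff=2.5)
        assert result.n_clusters == 1 and result.sizes == (5,)

    def test_hand_built_rmsd_structure(self):
        """Frames 0-2 mutually close, 3-4 close, groups far apart."""
        m = np.array(
            [
                [0.0, 1.0, 1.0, 9.0, 9.0],
                [1.0, 0.0, 1.0, 9.0, 9.0],
                [1.0, 1.0, 0.0, 9.0, 9.0],
                [9.0, 9.0, 9.0, 0.0, 1.0],
                [9.0, 9.0, 9.0, 1.0, 0.0],
            ]
        )
        traj = make_traj(np.zeros((5, 3, 3)))
        result = gromos_cluster(traj, cutoff=2.5, rmsd_matrix=m)
        assert result.sizes == (3, 2)
        assert set(result.members(0)) == {0, 1, 2}
        assert set(result.members(1)) == {3, 4}
        assert result.centroids[0] == 0  # tie on neighbor count -> lowest index

    def test_planted_two_cluster_recovery(self):
        traj, truth = gen_trajectory(TrajectorySimConfig(
            n_frames_per_replicate=25, n_replicates=2, n_centers=2, jitter_sd=0.1, seed=11
        ))
        assert not truth.clusters_may_overlap
        result = gromos_cluster(traj, cutoff=2.5)
        assert result.n_clusters == 2
        assert partitions_equal(result.assignment, truth.cluster_of_frame)
        # the reported first cluster is the largest
        assert result.sizes[0] == max(result.sizes)

    def test_single_center_single_cluster(self):
        traj, _ = gen_trajectory(TrajectorySimConfig(
            n_frames_per_replicate=10, n_replicates=1, n_centers=1, seed=3
        ))
        assert gromos_cluster(traj, cutoff=2.5).n_clusters == 1

    def test_matches_brute_force_on_random_trajectories(self, rng):
        for _ in range(100):
            coords = rng.normal(0, 2.0, size=(15, 4, 3))
            traj = make_traj(coords)
            m = pairwise_rmsd_matrix(traj)
            cutoff = float(rng.uniform(0.5, 4.0))
            result = gromos_cluster(traj, cutoff=cutoff, rmsd_matrix=m)
            expected = brute_force_gromos(m, cutoff)
            assert partitions_equal(result.assignment, expected)

    def test_invariants_members_within_cutoff_of_centroid(self, rng):
        coords = rng.normal(0, 2.0, size=(20, 4, 3))
        traj = make_traj(coords)
        m = pairwise_rmsd_matrix(traj)
        result = gromos_cluster(traj, cutoff=2.0, rmsd_matrix=m)
        assert (result.assignment >= 0).all()
        assert sum(result.sizes) == traj.n_frames
        assert list(result.sizes) == sorted(result.sizes, reverse=True)
        for k, centroid in enumerate(result.centroids):
            assert result.assignment[centroid] == k
            for member in result.members(k):
                assert m[centroid, member] <= 2.0

    def test_empty_trajectory_rejected(self):
        traj = make_traj(np.zeros((0, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            gromos_cluster(traj, cutoff=2.5)

    def test_nonpositive_cutoff_rejected(self, rng):
        traj = make_traj(rng.normal(size=(2, 3, 3)))
        with pytest.raises(ValueError, match="cutoff"):
            gromos_cluster(traj, cutoff=0.0)


class TestHbondOccupancy:
    @staticmethod
    def triple_traj(acceptor_positions, boundaries=()):
        """Donor at origin, hydrogen at (1,0,0), acceptor per frame."""
        n = len(acceptor_positions)
        coords = np.zeros((n, 3, 3))
        coords[:, 1, 0] = 1.0
        coords[:, 2] = acceptor_positions
        return Trajectory(
            coords=coords, labels=("D:1", "H:1", "A:2"), replicate_boundaries=boundaries
        )

    SPEC = HBondSpec(donor="D:1", hydrogen="H:1", acceptor="A:2")

    def test_always_satisfied_is_100_percent(self):
        traj = self.triple_traj([[2.9, 0, 0]] * 5)
        table, report = hbond_occupancy(traj, [self.SPEC])
        assert table["occupancy_pct"].iloc[0] == 100.0
        assert len(report) == 1

    def test_far_acceptor_is_zero_and_excluded(self):
        traj = self.triple_traj([[10.0, 0, 0]] * 5)
        table, report = hbond_occupancy(traj, [self.SPEC])
        assert table["occupancy_pct"].iloc[0] == 0.0
        assert len(report) == 0

    def test_angle_criterion_rejects_bent_geometry(self):
        # acceptor at 90 degrees from the D-H axis, within distance
        traj = self.triple_traj([[1.0, 1.5, 0]] * 4)
        table, _ = hbond_occupancy(traj, [self.SPEC])
        assert table["occupancy_pct"].iloc[0] == 0.0

    def test_planted_occupancy_recovered(self):
        traj, truth = gen_trajectory(TrajectorySimConfig(
            n_frames_per_replicate=100, n_replicates=2, n_centers=1,
            planted_hbonds=(("hb", 0.5),), seed=5
        ))
        table, report = hbond_occupancy(traj, truth.hbond_specs)
        assert table["occupancy_pct"].iloc[0] == pytest.approx(50.0)
        assert len(report) == 1

    def test_low_occupancy_excluded_from_report(self):
        traj, truth = gen_trajectory(TrajectorySimConfig(
            n_frames_per_replicate=100, n_replicates=1, n_centers=1,
            planted_hbonds=(("strong", 0.5), ("weak", 0.05)), seed=6
        ))
        table, report = hbond_occupancy(traj, truth.hbond_specs)
        assert len(table) == 2 and len(report) == 1
        assert report["occupancy_pct"].iloc[0] == pytest.approx(50.0)

    def test_pooled_occupancy_invariant_to_frame_order(self, rng):
        positions = [[2.9, 0, 0]] * 3 + [[10.0, 0, 0]] * 7
        perm = rng.permutation(10)
        t1 = self.triple_traj(positions)
        t2 = self.triple_traj([positions[i] for i in perm])
        occ1, _ = hbond_occupancy(t1, [self.SPEC])
        occ2, _ = hbond_occupancy(t2, [self.SPEC])
        assert occ1["occupancy_pct"].iloc[0] == occ2["occupancy_pct"].iloc[0] == 30.0

    def test_per_replicate_breakdown(self):
        positions = [[2.9, 0, 0]] * 4 + [[10.0, 0, 0]] * 4
        traj = self.triple_traj(positions, boundaries=(4,))
        table, _ = hbond_occupancy(traj, [self.SPEC])
        assert table["occupancy_pct_rep0"].iloc[0] == 100.0
        assert table["occupancy_pct_rep1"].iloc[0] == 0.0

    def test_unknown_atom_label_named(self):
        traj = self.triple_traj([[2.9, 0, 0]])
        bad = HBondSpec(donor="D:1", hydrogen="H:1", acceptor="Q:9")
        with pytest.raises(KeyError, match="Q:9"):
            hbond_occupancy(traj, [bad])

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            HBondSpec("D", "H", "A", distance_cutoff=-1)
        with pytest.raises(ValueError):
            HBondSpec("D", "H", "A", angle_cutoff=200)


class TestTrajectoryContainer:
    def test_boundary_validation(self, rng):
        coords = rng.normal(size=(4, 3, 3))
        labels = ["a:1", "b:1", "c:1"]
        with pytest.raises(ValueError):
            Trajectory(coords=coords, labels=labels, replicate_boundaries=(3, 2))
        with pytest.raises(ValueError):
            Trajectory(coords=coords, labels=labels, replicate_boundaries=(0,))

    def test_label_count_validation(self, rng):
        with pytest.raises(ValueError):
            Trajectory(coords=rng.normal(size=(2, 3, 3)), labels=("x:1",))


class TestTrajIO:
    def test_frames_table_round_trip(self, tmp_path, rng):
        traj = make_traj(rng.normal(size=(3, 4, 3)), boundaries=(2,))
        path = tmp_path / "frames.txt"
        traj_io.write_frames_table(traj, path)
        back = traj_io.read_frames_table(path, replicate_boundaries=(2,))
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-6)
        assert back.labels == traj.labels
        assert back.replicate_boundaries == (2,)

    def test_pdb_round_trip(self, tmp_path, rng):
        traj = make_traj(np.round(rng.normal(size=(2, 5, 3)), 3))
        path = tmp_path / "traj.pdb"
        traj_io.write_pdb(traj, path)
        back = traj_io.read_pdb(path)
        assert back.n_frames == 2 and back.n_atoms == 5
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-3)
        assert back.labels == traj.labels
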