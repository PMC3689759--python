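import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import oligotraj as ot
from oligotraj.conformation import cluster_from_distance_matrix
from oligotraj.core import Frame, Trajectory


def _random_rigid(rng):
    return Rotation.random(rng=rng).as_matrix(), rng.uniform(-10, 10, 3)


class TestKabsch:
    def test_identical_sets_have_zero_rmsd(self):
        rng = np.random.default_rng(30)
        x = rng.normal(size=(8, 3))
        rot, t, rmsd = ot.kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_rigid_copy_recovers_transform(self):
        rng = np.random.default_rng(31)
        x = rng.normal(size=(10, 3))
        r_true, t_true = _random_rigid(rng)
        y = x @ r_true.T + t_true  # y = R x + t  =>  x = R^T (y - t)
        rot, t, rmsd = ot.kabsch_superpose(x, y)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rot @ y.T + t[:, None], x.T, atol=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=(6, 3))
        y = x.copy()
        y[:, 0] *= -1  # mirrored set: best proper rotation must not reflect
        rot, _, _ = ot.kabsch_superpose(x, y)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_against_scipy_and_rotation_grid_oracle(self):
        """Perturbed 4-point sets: rmsd matches align_vectors and no grid
        rotation does better."""
        rng = np.random.default_rng(33)
        x = np.array([[0.0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0], [0, 3.8, 1.5]])
        y = x + rng.normal(0, 1.0, x.shape)
        _, _, rmsd = ot.kabsch_superpose(x, y)

        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        rot_sp, _ = Rotation.align_vectors(xc, yc)
        rmsd_sp = float(np.sqrt(((rot_sp.apply(yc) - xc) ** 2).sum(axis=1).mean()))
        assert rmsd == pytest.approx(rmsd_sp, abs=1e-3)

        grid_best = min(
            float(np.sqrt(((r.apply(yc) - xc) ** 2).sum(axis=1).mean()))
            for r in Rotation.random(4000, rng=np.random.default_rng(34))
        )
        assert rmsd <= grid_best + 1e-9

    def test_weighted_fit_prefers_heavy_points(self):
        x = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 0]])
        y = x.copy()
        y[3] += [0, 0, 2.0]
        w = np.array([1.0, 1.0, 1.0, 100.0])
        _, _, rmsd_w = ot.kabsch_superpose(x, y, weights=w)
        _, _, rmsd_u = ot.kabsch_superpose(x, y)
        assert rmsd_w != pytest.approx(rmsd_u)

    def test_errors(self):
        with pytest.raises(ValueError):
            ot.kabsch_superpose(np.zeros((3, 3)), np.zeros((4, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            ot.kabsch_superpose(line, line)


class TestRmsdSeries:
    def test_reference_against_itself(self, ordered_dimer):
        series = ot.rmsd_series(ordered_dimer, 0)
        assert series[0] == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_copies_are_all_zero(self, ordered_dimer):
        rng = np.random.default_rng(35)
        base = ordered_dimer.frames[0].coords
        frames = []
        for i in range(5):
            r, t = _random_rigid(rng)
            frames.append(Frame(float(i), base @ r.T + t))
        traj = Trajectory(ordered_dimer.topology, frames)
        np.testing.assert_allclose(ot.rmsd_series(traj, 0), 0.0, atol=1e-9)

    def test_matches_independent_fit_oracle_under_noise(self, ordered_dimer):
        """Fitted rmsd of noisy frames agrees with a scipy-based oracle."""
        rng = np.random.default_rng(36)
        base = ordered_dimer.frames[0].coords
        sigma = 0.5
        frames = [Frame(float(i), base + rng.normal(0, sigma, base.shape)) for i in range(20)]
        traj = Trajectory(ordered_dimer.topology, frames)
        series = ot.rmsd_series(traj, reference=Frame(0.0, base))

        idx = ot.select_atoms(traj, "name CA")
        ref = base[idx] - base[idx].mean(axis=0)
        oracle = []
        for f in frames:
            yc = f.coords[idx] - f.coords[idx].mean(axis=0)
            rot, _ = Rotation.align_vectors(ref, yc)
            oracle.append(np.sqrt(((rot.apply(yc) - ref) ** 2).sum(axis=1).mean()) / 10.0)
        np.testing.assert_allclose(series, oracle, rtol=1e-6)
        # fitting removes ~6 of the 3N noise degrees of freedom, so the mean
        # fitted rmsd approaches sigma * sqrt(3 - 6/N) (in nm here)
        n_fit = len(idx)
        expected = sigma * np.sqrt(3.0 - 6.0 / n_fit) / 10.0
        assert np.mean(series) == pytest.approx(expected, rel=0.1)

    def test_empty_selection_raises(self, ordered_dimer):
        with pytest.raises(ValueError, match="no atoms"):
            ot.rmsd_series(ordered_dimer, 0, selection="name XX")


def _brute_force_gromos(dist, cutoff):
    """Independent greedy clustering by explicit neighbor enumeration."""
    n = dist.shape[0]
    remaining = list(range(n))
    assignment = [-1] * n
    centers, populations = [], []
    while remaining:
        best_center, best_members = None, []
        for i in remaining:
            members = [j for j in remaining if dist[i, j] <= cutoff]
            if len(members) > len(best_members) or (
                len(members) == len(best_members)
                and (best_center is None or i < best_center)
            ):
                best_center, best_members = i, members
        for j in best_members:
            assignment[j] = len(centers)
        centers.append(best_center)
        populations.append(len(best_members))
        remaining = [j for j in remaining if j not in best_members]
    return assignment, centers, populations


class TestDauraClustering:
    def test_all_identical_frames_form_one_cluster(self, ordered_dimer):
        frames = [Frame(float(i), ordered_dimer.frames[0].coords.copy()) for i in range(6)]
        traj = Trajectory(ordered_dimer.topology, frames)
        result = ot.daura_cluster(traj, cutoff=0.2)
        assert len(result.centers) == 1
        assert result.populations == [6]

    def test_sub_minimal_cutoff_gives_singletons(self):
        rng = np.random.default_rng(37)
        n = 5
        dist = rng.uniform(1.0, 2.0, (n, n))
        dist = (dist + dist.T) / 2
        np.fill_diagonal(dist, 0.0)
        result = cluster_from_distance_matrix(dist, cutoff=0.5)
        assert len(result.centers) == n
        assert result.populations == [1] * n

    def test_two_well_separated_groups(self):
        dist = np.full((6, 6), 5.0)
        for group in ([0, 1, 2], [3, 4, 5]):
            for i in group:
                for j in group:
                    dist[i, j] = 0.1 if i != j else 0.0
        result = cluster_from_distance_matrix(dist, cutoff=0.2)
        assert result.populations == [3, 3]
        assert sorted(result.centers) == [0, 3]
        assignment, centers, populations = _brute_force_gromos(dist, 0.2)
        assert list(result.assignment) == assignment

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(38)
        for n in (2, 4, 6, 8):
            for _ in range(25):
                d = rng.uniform(0, 1, (n, n))
                d = (d + d.T) / 2
                np.fill_diagonal(d, 0.0)
                cutoff = float(rng.uniform(0.1, 0.9))
                got = cluster_from_distance_matrix(d, cutoff)
                assignment, centers, populations = _brute_force_gromos(d, cutoff)
                assert list(got.assignment) == assignment
                assert got.centers == centers
                assert got.populations == populations

    def test_populations_are_non_increasing(self):
        rng = np.random.default_rng(39)
        d = rng.uniform(0, 1, (8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        result = cluster_from_distance_matrix(d, 0.4)
        assert all(a >= b for a, b in zip(result.populations, result.populations[1:]))

    def test_permutation_gives_same_partition(self):
        rng = np.random.default_rng(40)
        d = rng.uniform(0, 1, (7, 7))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        base = cluster_from_distance_matrix(d, 0.45)
        perm = rng.permutation(7)
        permuted = cluster_from_distance_matrix(d[np.ix_(perm, perm)], 0.45)

        def partition(assignment):
            groups = {}
            for i, c in enumerate(assignment):
                groups.setdefault(c, set()).add(i)
            return {frozenset(g) for g in groups.values()}

        base_sets = partition(base.assignment)
        permuted_sets = {
            frozenset(int(perm[i]) for i in g) for g in partition(permuted.assignment)
        }
        assert base_sets == permuted_sets

    def test_pairwise_matrix_symmetry(self, scripted_dimer):
        _, traj = scripted_dimer
        sub = Trajectory(traj.topology, traj.frames[:6])
        d = ot.pairwise_rmsd_matrix(sub)
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert np.all(d >= 0)
        assert np.all(np.diag(d) == 0)
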