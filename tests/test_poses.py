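"""Pose analysis: superposition, PCA, X-means, pose ranking, f_int maps."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

import sonomd as smd
from sonomd.poses import PoseDataset


def random_structure(n, seed):
    return np.random.default_rng(seed).uniform(0, 5, (n, 3))


class TestSuperpose:
    def test_identity(self):
        ref = random_structure(20, 1)
        out, rmsd = smd.superpose(ref, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(out, ref)

    def test_pure_rotation_recovered(self):
        ref = random_structure(20, 2)
        rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.2]).as_matrix()
        mobile = ref @ rot.T + np.array([1.0, -2.0, 0.5])
        out, rmsd = smd.superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(out, ref, atol=1e-9)

    def test_noisy_rotation_matches_quaternion_oracle(self):
        """Kabsch RMSD equals the Theobald quaternion-based oracle."""
        rng = np.random.default_rng(3)
        ref = random_structure(30, 4)
        rot = Rotation.from_euler("xyz", [0.2, 0.9, -0.7]).as_matrix()
        mobile = ref @ rot.T + rng.normal(0, 0.1, (30, 3)) + 2.0
        _, rmsd = smd.superpose(mobile, ref)
        # oracle: quaternion eigenvalue method on centered coordinates
        a = mobile - mobile.mean(0)
        b = ref - ref.mean(0)
        m = a.T @ b
        sxx, sxy, sxz = m[0]
        syx, syy, syz = m[1]
        szx, szy, szz = m[2]
        k = np.array([
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
        lam = np.linalg.eigvalsh(k)[-1]
        ga = np.sum(a * a)
        gb = np.sum(b * b)
        oracle = np.sqrt(max(ga + gb - 2 * lam, 0.0) / len(ref))
        assert rmsd == pytest.approx(oracle, abs=1e-8)

    def test_rigid_transform_invariance(self):
        """Applying one rigid transform to both structures leaves RMSD fixed."""
        a, b = random_structure(15, 5), random_structure(15, 6)
        _, rmsd0 = smd.superpose(a, b)
        rot = Rotation.from_euler("zyx", [1.0, 0.3, -0.6]).as_matrix()
        _, rmsd1 = smd.superpose(a @ rot.T + 3.0, b @ rot.T + 3.0)
        assert rmsd1 == pytest.approx(rmsd0, rel=1e-9)

    def test_proper_rotation_enforced(self):
        ref = random_structure(20, 7)
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        out, _ = smd.superpose(mirrored, ref)
        # the fit may be poor but must not invert chirality
        v1, v2, v3 = out[1] - out[0], out[2] - out[0], out[3] - out[0]
        w1, w2, w3 = (mirrored[1] - mirrored[0], mirrored[2] - mirrored[0],
                      mirrored[3] - mirrored[0])
        assert np.sign(np.dot(np.cross(v1, v2), v3)) \
            == np.sign(np.dot(np.cross(w1, w2), w3))

    def test_collinear_selection_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError):
            smd.superpose(line, line + 1.0)


class TestLigandPCA:
    def test_single_axis_variation(self):
        t = np.linspace(-1, 1, 50)
        frames = np.outer(t, np.array([1.0, 0, 0, 1.0, 0, 0]))
        res = smd.ligand_pca(PoseDataset(frames))
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_planted_anisotropic_variances(self):
        """Variances 4:2:1 along orthogonal directions give fractions
        4/7, 2/7, 1/7."""
        rng = np.random.default_rng(8)
        n = 4000
        scores = rng.normal(0, 1, (n, 3)) * np.sqrt([4.0, 2.0, 1.0])
        basis = np.linalg.qr(rng.normal(size=(9, 9)))[0][:, :3]
        frames = scores @ basis.T
        res = smd.ligand_pca(PoseDataset(frames))
        assert np.allclose(res.variance_fractions,
                           [4 / 7, 2 / 7, 1 / 7], atol=0.02)

    def test_scores_covariance_diagonal(self):
        rng = np.random.default_rng(9)
        frames = rng.normal(0, 1, (300, 12)) * np.linspace(3, 0.1, 12)
        res = smd.ligand_pca(PoseDataset(frames), n_components=4)
        cov = np.cov(res.scores.T)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-8

    def test_crystal_pose_projection(self):
        rng = np.random.default_rng(10)
        frames = rng.normal(0, 1, (100, 6))
        ref = frames[0]
        res = smd.ligand_pca(PoseDataset(frames, reference=ref))
        expected = (ref - frames.mean(0)) @ res.eigenvectors
        assert np.allclose(res.crystal_scores, expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            smd.ligand_pca(PoseDataset(np.ones((10, 6))))


class TestXMeans:
    def test_recovers_planted_k_and_labels(self):
        """Well-separated planted Gaussians (10 sigma) are fully recovered."""
        points, truth, man = smd.planted_clusters(3, 150, 10.0, seed=11)
        labels, centroids, k = smd.xmeans(points, k_max=10, seed=0)
        assert k == 3
        # Hungarian matching of label permutation
        conf = np.zeros((3, 3), dtype=int)
        for t, l in zip(truth, labels):
            conf[t, l] += 1
        rows, cols = linear_sum_assignment(-conf)
        assert conf[rows, cols].sum() == len(points)

    def test_single_blob_one_cluster(self):
        points, _, _ = smd.planted_clusters(1, 200, 10.0, seed=12)
        _, _, k = smd.xmeans(points, k_max=8, seed=0)
        assert k == 1

    def test_deterministic_under_seed(self):
        points, _, _ = smd.planted_clusters(4, 80, 8.0, seed=13)
        out1 = smd.xmeans(points, k_max=10, seed=5)
        out2 = smd.xmeans(points, k_max=10, seed=5)
        assert np.array_equal(out1[0], out2[0])
        assert np.allclose(out1[1], out2[1])
        assert out1[2] == out2[2]

    def test_kmax_one_is_global_mean(self):
        points, _, _ = smd.planted_clusters(3, 50, 10.0, seed=14)
        labels, centroids, k = smd.xmeans(points, k_max=1, seed=0)
        assert k == 1
        assert np.allclose(centroids[0], points.mean(axis=0))
        assert np.all(labels == 0)


class TestRankPoses:
    def test_crystal_inside_cluster_is_pose_one(self):
        points, truth, man = smd.planted_clusters(3, 100, 12.0, seed=15)
        labels, centroids, k = smd.xmeans(points, k_max=8, seed=0)
        crystal = np.array(man["centers"])[1]     # sit in planted cluster 1
        ranks = smd.rank_poses(labels, centroids, crystal)
        # brute-force nearest centroid
        nearest = int(np.argmin(np.sum((centroids - crystal) ** 2, axis=1)))
        assert ranks[0] == nearest

    def test_tie_broken_by_cluster_size(self):
        labels = np.array([0, 0, 0, 1, 1])
        centroids = np.array([[1.0, 0.0], [-1.0, 0.0]])
        ranks = smd.rank_poses(labels, centroids, np.array([0.0, 0.0]))
        assert list(ranks) == [0, 1]    # equidistant; larger cluster first


class TestInteractionFrequency:
    def _window(self, ligand_xyz):
        return {"window": (0.0, 10.0), "rmsf": 0.1,
                "ligand_mean": np.asarray(ligand_xyz)}

    def test_definition_and_monotonicity(self):
        res_coords = {"R1": np.array([[0.0, 0.0, 0.0]]),
                      "R2": np.array([[5.0, 0.0, 0.0]])}
        w_close = self._window([[0.3, 0.0, 0.0]])
        f1 = smd.interaction_frequency([w_close], [res_coords],
                                       n_trajectories=10)
        assert f1["R1"] == pytest.approx(0.1)
        assert f1["R2"] == 0.0
        f2 = smd.interaction_frequency([w_close, w_close],
                                       [res_coords, res_coords],
                                       n_trajectories=10)
        assert f2["R1"] == pytest.approx(0.2)     # adding windows never lowers
        assert f2["R1"] >= f1["R1"] and f2["R2"] >= f1["R2"]

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(16)
        residues = {f"R{i}": rng.uniform(0, 3, (4, 3)) for i in range(6)}
        windows, coords = [], []
        for _ in range(5):
            windows.append(self._window(rng.uniform(0, 3, (3, 3))))
            coords.append(residues)
        f = smd.interaction_frequency(windows, coords, n_trajectories=5)
        for name, rc in residues.items():
            count = 0
            for w in windows:
                dmin = min(np.linalg.norm(a - l)
                           for a in rc for l in w["ligand_mean"])
                count += dmin < 0.5
            assert f[name] == pytest.approx(count / 5)

    def test_fraction_mode(self):
        res_coords = {"R1": np.array([[0.0, 0.0, 0.0]])}
        w = self._window([[0.1, 0.0, 0.0]])
        f = smd.interaction_frequency([w, w], [res_coords, res_coords],
                                      n_trajectories=99, mode="fraction")
        assert f["R1"] == 1.0


class TestSpecificSites:
    def test_planted_two_site_fixture(self):
        """Shared hot residue excluded as nonspecific; disjoint targets kept."""
        maps = {
            "ligA": {"SHARED": 0.5, "A1": 0.4, "A2": 0.2, "B1": 0.0},
            "ligB": {"SHARED": 0.6, "A1": 0.0, "A2": 0.05, "B1": 0.3},
        }
        result = smd.specific_sites(maps, nonspecific_threshold=0.1)
        assert result.nonspecific == ["SHARED"]
        assert result.specific["ligA"] == ["A1", "A2"]
        assert result.specific["ligB"] == ["B1", "A2"]

    def test_residue_hot_for_one_ligand_is_specific(self):
        maps = {"a": {"R": 0.5}, "b": {"R": 0.0}}
        result = smd.specific_sites(maps)
        assert result.nonspecific == []
        assert result.specific["a"] == ["R"]

    def test_needs_two_ligands(self):
        with pytest.raises(ValueError):
            smd.specific_sites({"only": {"R": 1.0}})
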