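import numpy as np
import pytest

from ppidyn.essential import (
    BOLTZMANN_KCAL,
    fel,
    fit_pca,
    kmeans_representatives,
    overlap_matrix,
    porcupine,
    project,
    rmsip,
    variance_fractions,
    ProjectionSeries,
)
from ppidyn.structio import TrajectoryEnsemble


def _traj(model, disp):
    return TrajectoryEnsemble(model, model.coordinates[None] + disp)


def _mode(n_atoms, rng=None, vec=None):
    if vec is None:
        vec = rng.normal(size=(n_atoms, 3))
    return vec / np.linalg.norm(vec)


class TestFitPca:
    def test_rank_one_construction(self, toy_complex, rng):
        v = _mode(8, rng)
        amps = np.array([1.0, -1.0] * 10)
        disp = amps[:, None, None] * v[None]
        model = fit_pca(_traj(toy_complex, disp), np.arange(8), fit=False)
        assert model.eigenvalues[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(model.eigenvalues[1:] <= 1e-12)
        pc1 = model.eigenvectors[:, 0].reshape(-1, 3)
        assert np.allclose(np.abs(pc1.ravel() @ v.ravel()), 1.0, atol=1e-9)

    def test_two_mode_variance_ratio(self, toy_complex, rng):
        v1 = np.zeros((8, 3)); v1[:4, 0] = 0.5
        v2 = np.zeros((8, 3)); v2[4:, 1] = 0.5
        v1, v2 = _mode(8, vec=v1), _mode(8, vec=v2)
        n = 5000
        disp = (
            rng.normal(0, 2.0, n)[:, None, None] * v1[None]
            + rng.normal(0, 1.0, n)[:, None, None] * v2[None]
        )
        model = fit_pca(_traj(toy_complex, disp), np.arange(8), fit=False)
        ratio = model.eigenvalues[0] / model.eigenvalues[1]
        assert ratio == pytest.approx(4.0, rel=0.05)
        fr = variance_fractions(model)
        assert fr[0] == pytest.approx(0.8, abs=0.02)
        assert fr[1] == pytest.approx(0.2, abs=0.02)

    def test_pooling_with_itself_identical(self, toy_complex, rng):
        disp = rng.normal(0, 0.5, size=(100, 8, 3))
        t = _traj(toy_complex, disp)
        sel = np.arange(8)
        ref = t.frames[0]
        m1 = fit_pca(t, sel, reference=ref[sel])
        m2 = fit_pca([t, t], sel, reference=ref[sel])
        assert np.allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-9)
        # eigenvectors compared on the non-degenerate leading spectrum only
        # (the fitted-out rigid-body dimensions are a degenerate eigenspace)
        assert np.allclose(m1.eigenvectors[:, :10], m2.eigenvectors[:, :10], atol=1e-7)

    def test_eigenvalue_sum_equals_trace(self, toy_complex, rng):
        disp = rng.normal(0, 0.5, size=(200, 8, 3))
        t = _traj(toy_complex, disp)
        model = fit_pca(t, np.arange(8))
        from ppidyn.fitmetrics import superpose_frames

        fitted = superpose_frames(t.frames, t.frames[0])
        x = (fitted - fitted.mean(axis=0)).reshape(200, -1)
        trace = np.sum(x * x) / 200
        assert model.eigenvalues.sum() == pytest.approx(trace, rel=1e-9)


class TestVarianceFractions:
    def test_rank_one_is_unity(self, toy_complex, rng):
        v = _mode(8, rng)
        disp = np.array([1.0, -1.0, 2.0, -2.0])[:, None, None] * v[None]
        model = fit_pca(_traj(toy_complex, disp), np.arange(8), fit=False)
        assert variance_fractions(model)[0] == pytest.approx(1.0, abs=1e-12)

    def test_fractions_sum_to_one(self, toy_complex, rng):
        disp = rng.normal(size=(50, 8, 3))
        model = fit_pca(_traj(toy_complex, disp), np.arange(8))
        assert variance_fractions(model).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_errors(self, toy_complex):
        disp = np.zeros((5, 8, 3))
        model = fit_pca(_traj(toy_complex, disp), np.arange(8))
        with pytest.raises(ValueError):
            variance_fractions(model)


class TestProject:
    def test_mean_projects_to_zero(self, toy_complex, rng):
        disp = rng.normal(size=(50, 8, 3))
        model = fit_pca(_traj(toy_complex, disp), np.arange(8))
        proj = project(model, model.mean_coordinates[None], components=(0, 1))
        assert np.allclose(proj.scores, 0.0, atol=1e-9)

    def test_known_displacement_scores(self, toy_complex, rng):
        disp = rng.normal(size=(60, 8, 3))
        model = fit_pca(_traj(toy_complex, disp), np.arange(8))
        frame = model.mean_coordinates + 2.0 * model.eigenvectors[:, 0].reshape(-1, 3)
        proj = project(model, frame[None], components=(0, 1), fit=False)
        assert proj.scores[0, 0] == pytest.approx(2.0, abs=1e-6)
        assert proj.scores[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_full_basis_reconstruction(self, toy_complex, rng):
        disp = rng.normal(0, 0.2, size=(30, 8, 3))
        t = _traj(toy_complex, disp)
        model = fit_pca(t, np.arange(8))
        from ppidyn.fitmetrics import superpose_frames

        fitted = superpose_frames(t.frames, model.mean_coordinates)
        proj = project(model, t, components=range(24), selection=np.arange(8))
        recon = model.mean_coordinates.ravel()[None] + proj.scores @ model.eigenvectors.T
        assert np.allclose(recon, fitted.reshape(30, -1), atol=1e-9)


class TestSubspaceComparison:
    def _model(self, toy_complex, rng, scale=1.0):
        disp = rng.normal(0, scale, size=(100, 8, 3))
        return fit_pca(_traj(toy_complex, disp), np.arange(8))

    def test_self_rmsip_is_one(self, toy_complex, rng):
        m = self._model(toy_complex, rng)
        assert rmsip(m, m, k=10) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_subspaces_zero(self, toy_complex, rng):
        # block-disjoint displacements make strictly disjoint eigenvector support
        d1 = np.zeros((50, 8, 3)); d1[:, :4] = rng.normal(size=(50, 4, 3))
        d2 = np.zeros((50, 8, 3)); d2[:, 4:] = rng.normal(size=(50, 4, 3))
        m1 = fit_pca(TrajectoryEnsemble(toy_complex, d1 + toy_complex.coordinates), np.arange(8), fit=False)
        m2 = fit_pca(TrajectoryEnsemble(toy_complex, d2 + toy_complex.coordinates), np.arange(8), fit=False)
        # compare leading k=3 of each (well within each block's rank), no fitting noise
        ov = overlap_matrix(m1, m2, k=3)
        assert rmsip(m1, m2, k=3) == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(ov, 0.0, atol=1e-12)

    def test_known_angle_single_mode(self, toy_complex):
        theta = np.deg2rad(60)
        v1 = np.zeros(24); v1[0] = 1.0
        v2 = np.zeros(24); v2[0] = np.cos(theta); v2[3] = np.sin(theta)
        from ppidyn.essential import EssentialModel

        mean = toy_complex.coordinates
        m1 = EssentialModel(mean, v1[:, None], np.array([1.0]), [])
        m2 = EssentialModel(mean, v2[:, None], np.array([1.0]), [])
        assert rmsip(m1, m2, k=1) == pytest.approx(0.5, abs=1e-12)

    def test_overlap_identity_and_mean_identity(self, toy_complex, rng):
        m = self._model(toy_complex, rng)
        ov = overlap_matrix(m, m, k=5)
        assert np.allclose(ov, np.eye(5), atol=1e-9)
        m2 = self._model(toy_complex, np.random.default_rng(7))
        ov12 = overlap_matrix(m, m2, k=5)
        assert ov12.mean() * 25 / 5 == pytest.approx(rmsip(m, m2, k=5) ** 2, abs=1e-12)

    def test_rmsip_bounded_over_random_pairs(self, toy_complex):
        for seed in range(10):
            r = np.random.default_rng(seed)
            m1 = self._model(toy_complex, r)
            m2 = self._model(toy_complex, r)
            val = rmsip(m1, m2, k=5)
            assert 0.0 <= val <= 1.0 + 1e-12


class TestPorcupine:
    def test_planted_mode_recovered(self, toy_complex, rng, tmp_path):
        v = _mode(8, rng)
        disp = np.array([1.0, -1.0])[:, None, None] * v[None]
        model = fit_pca(_traj(toy_complex, disp), np.arange(8), fit=False)
        vecs = porcupine(model, 0, scale=1.0)
        # sign convention: largest-|loading| positive
        flat = model.eigenvectors[:, 0]
        assert flat[np.argmax(np.abs(flat))] > 0
        assert np.allclose(np.abs(vecs.ravel() @ v.ravel()), 1.0, atol=1e-9)
        path = tmp_path / "porc.pdb"
        porcupine(model, 0, scale=1.0, topology=toy_complex, selection=np.arange(8), path=path)
        from ppidyn.structio import read_structure, read_trajectory

        two = read_trajectory(path, toy_complex)
        assert two.n_frames == 2

    def test_zero_scale(self, toy_complex, rng):
        disp = rng.normal(size=(10, 8, 3))
        model = fit_pca(_traj(toy_complex, disp), np.arange(8))
        assert np.allclose(porcupine(model, 0, scale=0.0), 0.0)


class TestFel:
    def test_single_occupied_bin(self):
        grid = fel(np.zeros(100), np.zeros(100), bins=5, temperature=310.0)
        occupied = ~np.isnan(grid.G)
        assert occupied.sum() == 1
        assert grid.G[occupied][0] == 0.0

    def test_two_equal_bins_both_zero(self):
        a = np.array([0.0] * 50 + [10.0] * 50)
        grid = fel(a, np.zeros(100), bins=2)
        vals = grid.G[~np.isnan(grid.G)]
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_boltzmann_bin_closed_form(self):
        # a bin at N_i = N_m / e sits exactly k_B·T above the minimum
        n_m = 100_000
        n_i = int(round(n_m / np.e))
        a = np.repeat([0.0, 10.0], [n_m, n_i])
        grid = fel(a, np.zeros_like(a), bins=2, temperature=310.0)
        vals = np.sort(grid.G[~np.isnan(grid.G)])
        assert vals[0] == 0.0
        assert vals[1] == pytest.approx(BOLTZMANN_KCAL * 310.0, abs=1e-4)  # 0.6160

    def test_gaussian_well_curvature(self):
        rng = np.random.default_rng(42)
        sigma, T, n = 1.3, 310.0, 100_000
        x = rng.normal(0, sigma, n)
        grid = fel(x, np.zeros(n), bins=(50, 2), temperature=T)
        centers = grid.centers_a
        g = np.where(np.isnan(grid.G[:, 0]), grid.G[:, 1], grid.G[:, 0])
        ok = ~np.isnan(g) & (grid.counts.sum(axis=1) > 200)
        coef = np.polyfit(centers[ok], g[ok], 2)
        curvature = 2.0 * coef[0]
        assert curvature == pytest.approx(BOLTZMANN_KCAL * T / sigma**2, rel=0.10)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            fel(np.array([]), np.array([]))


class TestKmeans:
    def test_k1_centroid_is_mean(self, rng):
        x = rng.normal(size=(100, 2))
        summary = kmeans_representatives(ProjectionSeries(x, [0, 1]), k=1, seed=0)
        assert np.allclose(summary.centroids[0], x.mean(axis=0), atol=1e-9)
        assert summary.occupancy_percent[0] == pytest.approx(100.0)

    def test_separated_blobs_exact_occupancies(self, rng):
        centers = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
        sizes = [60, 30, 10]
        pts = np.concatenate(
            [c + rng.normal(0, 1.0, size=(s, 2)) for c, s in zip(centers, sizes)]
        )
        summary = kmeans_representatives(ProjectionSeries(pts, [0, 1]), k=3, seed=1)
        assert np.allclose(sorted(summary.occupancy_percent), [10.0, 30.0, 60.0])
        assert summary.occupancy_percent.sum() == pytest.approx(100.0, abs=0.01)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(200, 2))
        s1 = kmeans_representatives(ProjectionSeries(x, [0, 1]), k=5, seed=3)
        s2 = kmeans_representatives(ProjectionSeries(x, [0, 1]), k=5, seed=3)
        assert np.array_equal(s1.labels, s2.labels)
        assert np.allclose(s1.centroids, s2.centroids)
        assert np.array_equal(s1.medoid_frames, s2.medoid_frames)

    def test_k_exceeding_frames_errors(self, rng):
        x = rng.normal(size=(3, 2))
        with pytest.raises(ValueError):
            kmeans_representatives(ProjectionSeries(x, [0, 1]), k=5)

    def test_medoids_are_members(self, rng):
        x = rng.normal(size=(50, 2))
        s = kmeans_representatives(ProjectionSeries(x, [0, 1]), k=4, seed=0)
        for c in range(4):
            assert s.labels[s.medoid_frames[c]] == c
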