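import numpy as np
import pytest
from scipy import stats

from flexitomo.confspace import (
    EllipseRegion, FSCCurve, Trajectory, animate_trajectory, average_group,
    fit_trajectory, fsc, inverse_map, load_space, mahalanobis_filter,
    pca_fit_project, plot_space, resolution_at, save_space, select_group,
    soft_spherical_mask,
)
from flexitomo.nma import select_modes
from flexitomo.structures import DensityVolume
from flexitomo.tomosim import (
    RigidParams, Subtomogram, WedgeDescriptor, rotate_shift_volume, wedge_mask,
)


class TestPCA:
    def test_collinear_data_captured_by_first_component(self, rng):
        t = rng.normal(size=100)
        X = np.outer(t, [3.0, -1.0, 2.0]) + 5.0
        sp = pca_fit_project(X, d=2)
        assert sp.explained_variance[0] / sp.explained_variance.sum() > 0.999

    def test_full_rank_round_trip(self, rng):
        X = rng.normal(size=(50, 4))
        sp = pca_fit_project(X, d=4)
        back = inverse_map(sp, sp.points)
        np.testing.assert_allclose(back, X, atol=1e-10)

    def test_eigenvalues_match_covariance_oracle(self, rng):
        X = rng.normal(size=(50, 4)) @ np.diag([3.0, 1.0, 0.5, 0.2])
        sp = pca_fit_project(X, d=4)
        brute = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(sp.explained_variance, brute, atol=1e-10)

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(40, 3))
        a = pca_fit_project(X, d=2)
        b = pca_fit_project(-(-X), d=2)
        np.testing.assert_array_equal(a.basis, b.basis)
        for j in range(2):
            i = np.argmax(np.abs(a.basis[:, j]))
            assert a.basis[i, j] > 0

    def test_mean_projects_to_origin(self, rng):
        X = rng.normal(size=(30, 3)) + [10.0, -5.0, 2.0]
        sp = pca_fit_project(X, d=2)
        np.testing.assert_allclose(sp.points.mean(axis=0), 0.0, atol=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pca_fit_project(np.zeros((2, 3)), d=2)


class TestMahalanobis:
    def test_sample_mean_point_has_distance_zero(self):
        # symmetric data: the mean coincides with the middle point
        X = np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0],
                      [0.0, -1.0], [0.0, 1.0]])
        inlier, p = mahalanobis_filter(X, p_threshold=0.01)
        assert p[1] == pytest.approx(1.0)
        assert inlier[1]

    def test_chi_square_coverage_on_gaussian_sample(self, rng):
        X = rng.multivariate_normal([0, 0, 0], np.diag([4.0, 1.0, 0.25]), 2000)
        inlier, _ = mahalanobis_filter(X, p_threshold=0.01)
        assert inlier.mean() == pytest.approx(0.99, abs=0.02)

    def test_pvalues_match_chi2_formula(self, rng):
        X = rng.normal(size=(60, 3))
        _, p = mahalanobis_filter(X, 0.01)
        mu = X.mean(axis=0)
        cinv = np.linalg.inv(np.cov(X, rowvar=False))
        d2 = np.array([(x - mu) @ cinv @ (x - mu) for x in X])
        np.testing.assert_allclose(p, stats.chi2.sf(d2, 3), atol=1e-12)

    def test_singular_covariance_warns(self):
        X = np.zeros((10, 2))
        X[:, 0] = np.arange(10)  # second coordinate constant -> singular
        with pytest.warns(UserWarning, match="singular"):
            mahalanobis_filter(X, 0.01)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            mahalanobis_filter(np.zeros((3, 3)), 0.01)


class TestGrouping:
    def test_region_covering_everything_returns_all_inliers(self, rng):
        X = rng.normal(size=(40, 2))
        sp = pca_fit_project(X, d=2)
        sp.inlier = np.ones(40, dtype=bool)
        sp.inlier[7] = False
        idx = select_group(sp, EllipseRegion((0, 0), (100, 100)))
        assert len(idx) == 39 and 7 not in idx

    def test_disjoint_regions_are_disjoint(self, rng):
        X = np.concatenate([rng.normal(-5, 0.3, (20, 2)),
                            rng.normal(5, 0.3, (20, 2))])
        sp = pca_fit_project(X, d=2)
        left = select_group(sp, EllipseRegion((sp.points[:20, 0].mean(), 0), (3, 3)))
        right = select_group(sp, EllipseRegion((sp.points[20:, 0].mean(), 0), (3, 3)))
        assert set(left).isdisjoint(set(right))
        assert len(left) and len(right)

    def test_ccc_subfilter(self, rng):
        X = rng.normal(size=(20, 2))
        sp = pca_fit_project(X, d=2, ccc=np.linspace(0, 1, 20))
        idx = select_group(sp, EllipseRegion((0, 0), (100, 100)), min_ccc=0.5)
        assert all(sp.ccc[i] >= 0.5 for i in idx)


class TestAveraging:
    def test_identical_posed_items_average_to_member(self, phantom32):
        wd = WedgeDescriptor(-90, 90)
        subs = [Subtomogram(phantom32.copy(), wd) for _ in range(3)]
        rigids = [RigidParams() for _ in range(3)]
        avg = average_group(subs, rigids)
        np.testing.assert_allclose(avg.data, phantom32.data, atol=1e-5)

    def test_noise_reduction_scales_inversely_with_n(self, phantom32, rng):
        wd = WedgeDescriptor(-90, 90)
        n_copies = 16
        noisy = [
            Subtomogram(DensityVolume(
                phantom32.data + rng.normal(0, 1.0, phantom32.data.shape)
                .astype(np.float32), 2.0), wd)
            for _ in range(n_copies)
        ]
        rigids = [RigidParams() for _ in range(n_copies)]
        avg = average_group(noisy, rigids)
        residual = np.var(avg.data - phantom32.data)
        assert residual == pytest.approx(1.0 / n_copies, rel=0.3)

    def test_wedge_fill_restores_full_fourier_support(self, phantom32, rng):
        wd = WedgeDescriptor(-60, 60)
        m = wedge_mask(32, wd)
        filt = np.fft.ifftn(np.fft.fftn(phantom32.data.astype(float)) * m).real
        # identically oriented items: the unfilled average keeps the wedge
        subs = [Subtomogram(DensityVolume(filt.astype(np.float32), 2.0), wd)
                for _ in range(3)]
        rigids = [RigidParams() for _ in range(3)]
        unfilled = average_group(subs, rigids)
        Fu = np.abs(np.fft.fftn(unfilled.data.astype(float)))
        assert (Fu[~m] < 1e-3 * Fu[m].mean()).mean() > 0.99

        filled = average_group(subs, rigids, wedge_fill=True,
                               global_average=phantom32)
        Ff = np.abs(np.fft.fftn(filled.data.astype(float)))
        k = np.fft.fftfreq(32) * 32
        kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
        ball = np.sqrt(kx**2 + ky**2 + kz**2) <= 12
        assert (Ff[ball] > 1e-6 * Ff.max()).mean() > 0.999

    def test_wedge_fill_requires_global_average(self, phantom32):
        subs = [Subtomogram(phantom32, WedgeDescriptor(-60, 60))]
        with pytest.raises(ValueError):
            average_group(subs, [RigidParams()], wedge_fill=True)

    def test_empty_group_rejected(self, phantom32):
        with pytest.raises(ValueError):
            average_group([Subtomogram(phantom32, WedgeDescriptor(-60, 60))],
                          [RigidParams()], indices=[])

    def test_average_undoes_rigid_poses(self, phantom32):
        wd = WedgeDescriptor(-90, 90)
        rigids = [RigidParams((30.0, 45.0, 60.0), (1.0, -1.0, 0.0)),
                  RigidParams((200.0, 100.0, 10.0), (0.0, 2.0, -1.0))]
        subs = [Subtomogram(rotate_shift_volume(phantom32, rp), wd)
                for rp in rigids]
        avg = average_group(subs, rigids)
        c = np.corrcoef(avg.data.ravel(), phantom32.data.ravel())[0, 1]
        assert c > 0.98


class TestTrajectory:
    def test_endpoints_reproduce_data_points_at_full_rank(self, rng):
        X = rng.normal(size=(20, 3))
        sp = pca_fit_project(X, d=3)
        traj = fit_trajectory(sp.points[[2, 11]], n_frames=2)
        amps = inverse_map(sp, traj.sample())
        np.testing.assert_allclose(amps[0], X[2], atol=1e-10)
        np.testing.assert_allclose(amps[-1], X[11], atol=1e-10)

    def test_default_frame_count_is_ten(self):
        traj = fit_trajectory([[0.0, 0.0], [1.0, 0.0]])
        assert traj.sample().shape == (10, 2)

    def test_arc_length_uniform_sampling(self):
        # an L-shaped path: frames must be equally spaced along the length
        traj = Trajectory(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0]]),
                          n_frames=7)
        pts = traj.sample()
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        np.testing.assert_allclose(seg, seg[0], atol=1e-10)

    def test_straight_line_gives_uniform_amplitude_steps(self, rng):
        t = np.linspace(-1, 1, 30)
        X = np.outer(t, [50.0, 20.0])  # one-dimensional amplitude family
        sp = pca_fit_project(X, d=1)
        traj = fit_trajectory([sp.points.min(axis=0), sp.points.max(axis=0)],
                              n_frames=5)
        amps = inverse_map(sp, traj.sample())
        steps = np.diff(amps, axis=0)
        np.testing.assert_allclose(steps - steps[0], 0.0, atol=1e-6)

    def test_animation_deforms_reference(self, small_ref, small_modes, rng):
        sel = select_modes(small_modes, 2)
        X = rng.normal(0, 50, size=(20, 2))
        sp = pca_fit_project(X, d=2)
        traj = fit_trajectory(sp.points[[0, 5]], n_frames=4)
        frames = animate_trajectory(traj, sp, small_ref, small_modes, sel)
        assert len(frames) == 4
        assert not np.allclose(frames[0].coords, frames[-1].coords)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([[0.0, 0.0]]))

    def test_too_few_frames_rejected(self):
        traj = fit_trajectory([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            traj.sample(1)


class TestFSC:
    def test_self_correlation_is_one_everywhere(self, phantom32):
        curve = fsc(phantom32, phantom32)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-10)
        res, crossed = resolution_at(curve)
        assert not crossed
        assert res == pytest.approx(2 * phantom32.voxel_size)

    def test_independent_noise_decorrelates(self, rng):
        a = DensityVolume(rng.normal(size=(32, 32, 32)).astype(np.float32), 2.0)
        b = DensityVolume(rng.normal(size=(32, 32, 32)).astype(np.float32), 2.0)
        curve = fsc(a, b)
        assert np.abs(curve.values[3:]).max() < 0.25
        assert np.abs(curve.values[3:]).mean() < 0.1

    def test_resolution_interpolates_between_shells(self):
        freq = np.array([0.0, 0.1, 0.2])
        curve = FSCCurve(freq, np.array([1.0, 0.5, 0.0]), 2.5)
        res, crossed = resolution_at(curve, threshold=0.25)
        assert crossed
        assert res == pytest.approx(1.0 / 0.15)

    def test_low_pass_filtering_worsens_resolution(self, phantom32, rng):
        noisy = DensityVolume(
            (phantom32.data + rng.normal(0, 0.02, phantom32.data.shape))
            .astype(np.float32), 2.0)
        res_raw, _ = resolution_at(fsc(phantom32, noisy), 0.143)
        k = np.fft.fftfreq(32)
        kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
        lp = np.fft.ifftn(np.fft.fftn(noisy.data.astype(float))
                          * (np.sqrt(kx**2 + ky**2 + kz**2) < 0.15)).real
        res_lp, _ = resolution_at(
            fsc(phantom32, DensityVolume(lp.astype(np.float32), 2.0)), 0.143)
        assert res_lp > res_raw

    def test_grid_mismatch_rejected(self, phantom32):
        small = DensityVolume(np.zeros((16, 16, 16)), 2.0)
        with pytest.raises(ValueError):
            fsc(phantom32, small)

    def test_soft_mask_shape(self):
        m = soft_spherical_mask(32, radius=10, soft_sigma=2.0)
        assert m.shape == (32, 32, 32)
        assert m[16, 16, 16] == pytest.approx(1.0, abs=1e-3)
        assert m[0, 0, 0] == pytest.approx(0.0, abs=1e-3)


def test_space_persistence_roundtrip(tmp_path, rng):
    X = rng.normal(size=(25, 3))
    sp = pca_fit_project(X, d=2, ccc=rng.uniform(0, 1, 25))
    sp.inlier, sp.p_values = mahalanobis_filter(X, 0.01)
    path = tmp_path / "space.tsv"
    save_space(sp, path)
    back = load_space(path)
    np.testing.assert_allclose(back.points, sp.points, atol=1e-12)
    np.testing.assert_allclose(back.basis, sp.basis, atol=1e-12)
    np.testing.assert_array_equal(back.inlier, sp.inlier)


def test_plot_space_writes_image(tmp_path, rng):
    X = rng.normal(size=(30, 3))
    sp = pca_fit_project(X, d=2, ccc=rng.uniform(0, 1, 30))
    sp.inlier = np.ones(30, dtype=bool)
    sp.inlier[0] = False
    out = tmp_path / "space.png"
    plot_space(sp, out)
    assert out.exists() and out.stat().st_size > 0
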