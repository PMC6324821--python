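import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from chromotrace import density, metrics
from chromotrace.density import DensityMap


def blob_map(center, rng, n=400, scale=60.0, **kw):
    pts = rng.normal(scale=scale, size=(n, 3)) + center
    return density.build_map(pts, sigma=30.0, voxel_size=25.0, **kw)


def boxed_map(mask_slices, shape=(20, 20, 20), voxel=25.0):
    grid = np.zeros(shape)
    grid[mask_slices] = 10.0
    return DensityMap(grid, np.zeros(3), voxel, iso_threshold=1.0)


class TestDistanceScore:
    def test_identical_maps_zero(self, rng):
        m = blob_map([0, 0, 0], rng)
        assert metrics.distance_score(m, m) == 0.0

    def test_translation_equivariance(self):
        a = boxed_map((slice(4, 8), slice(4, 8), slice(4, 8)))
        b = boxed_map((slice(10, 14), slice(4, 8), slice(4, 8)))
        assert metrics.distance_score(a, b) == pytest.approx(6 * 25.0)

    def test_matches_brute_force_com(self, rng):
        a = blob_map([0, 0, 0], rng)
        b = blob_map([200, 100, -50], rng)
        def com(m):
            mask = m.body_mask()
            w = np.where(mask, m.data, 0.0)
            idx = np.indices(m.shape).reshape(3, -1).T
            return m.origin + ((idx * w.ravel()[:, None]).sum(0) / w.sum() + 0.5) * m.voxel_size
        want = np.linalg.norm(com(a) - com(b))
        assert metrics.distance_score(a, b) == pytest.approx(want, rel=1e-9)


class TestEntanglementScore:
    def test_identical_maps_full_overlap(self, rng):
        m = blob_map([0, 0, 0], rng)
        assert metrics.entanglement_score(m, m) == 1.0

    def test_disjoint_bodies(self):
        a = boxed_map((slice(2, 6), slice(2, 6), slice(2, 6)))
        b = boxed_map((slice(12, 16), slice(12, 16), slice(12, 16)))
        assert metrics.entanglement_score(a, b) == 0.0

    def test_containment_and_half_overlap(self):
        # A-body 100 voxels fully containing a 50-voxel B-body -> 1.0
        a = boxed_map((slice(0, 4), slice(0, 5), slice(0, 5)))   # 100 voxels
        b = boxed_map((slice(1, 3), slice(0, 5), slice(0, 5)))   # 50 voxels
        assert metrics.entanglement_score(a, b) == 1.0
        # B shifted so 25 of its 50 voxels overlap -> 0.5
        b2 = boxed_map((slice(3, 5), slice(0, 5), slice(0, 5)))
        assert metrics.entanglement_score(a, b2) == 0.5


class TestSphericity:
    def test_sphere_is_one_closed_form(self):
        for R in (1.0, 250.0, 8000.0):
            V, A = 4 / 3 * np.pi * R ** 3, 4 * np.pi * R ** 2
            assert metrics.sphericity(V, A) == pytest.approx(1.0, abs=1e-9)

    def test_unit_cube_closed_form(self):
        assert metrics.sphericity(1.0, 6.0) == pytest.approx(0.80600, abs=1e-3)

    def test_inverse_linear_in_area(self):
        assert metrics.sphericity(1.0, 3.0) == pytest.approx(
            2 * metrics.sphericity(1.0, 6.0))

    def test_voxelized_ball(self):
        R, v = 500.0, 20.0  # voxel <= R/20
        n = int(np.ceil(2 * R / v)) + 4
        c = (np.arange(n) + 0.5) * v - n * v / 2
        xx, yy, zz = np.meshgrid(c, c, c, indexing="ij")
        grid = ((xx ** 2 + yy ** 2 + zz ** 2) <= R ** 2).astype(float)
        m = DensityMap(grid, np.zeros(3), v, iso_threshold=0.5)
        psi = metrics.sphericity(density.body_volume(m), density.surface_area(m))
        assert psi == pytest.approx(1.0, abs=0.03)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            metrics.sphericity(0.0, 1.0)


class TestPowerLaw:
    def test_exact_points_give_zero_z(self):
        x = np.array([1e5, 3e5, 9e5, 2.7e6])
        y = 2.0 * x ** 0.5
        z = metrics.size_corrected_zscore(y, x)
        np.testing.assert_allclose(z, 0.0, atol=1e-9)

    def test_exponent_recovery_with_noise(self, rng):
        x = rng.uniform(1e5, 2e6, size=300)
        y = 2.0 * x ** 0.5 * rng.lognormal(sigma=0.2, size=300)
        fit = metrics.fit_power_law(x, y)
        assert fit.b == pytest.approx(0.5, rel=0.05)

    def test_underdetermined_fit_rejected(self):
        with pytest.raises(ValueError):
            metrics.fit_power_law([1.0, 2.0], [1.0, 2.0])

    def test_zscores_standardized_over_population(self, rng):
        x = rng.uniform(1e5, 2e6, size=500)
        y = 3.0 * x ** 0.4 + rng.normal(scale=5.0, size=500)
        z = metrics.size_corrected_zscore(y, x)
        assert abs(z.mean()) < 3 / np.sqrt(500)
        assert z.std() == pytest.approx(1.0, abs=0.1)


class TestSpatialOverlap:
    def test_identical_clusters(self, rng):
        pts = rng.normal(scale=100, size=(300, 3))
        assert metrics.spatial_overlap(pts, pts) == 1.0
        assert metrics.spatial_overlap(pts, pts, align=True) == 1.0

    def test_disjoint_clusters(self, rng):
        a = rng.normal(scale=50, size=(200, 3))
        b = a + [2000.0, 0, 0]
        assert metrics.spatial_overlap(a, b) == 0.0
        # centroid alignment makes the copies coincide
        assert metrics.spatial_overlap(a, b, align=True) == 1.0

    def test_directed_fraction_average(self, rng):
        # bodies are alpha-dilated, so points of A within alpha of B count
        a = rng.uniform([0, 0, 0], [1000, 400, 400], size=(1500, 3))
        b = rng.uniform([600, 0, 0], [1600, 400, 400], size=(1500, 3))
        got = metrics.spatial_overlap(a, b, alpha=150.0)
        # expected: mean of the two directed containment fractions,
        # each ~ (overlap span + alpha) / span of the cloud
        want = (400 + 150) / 1000
        assert got == pytest.approx(want, abs=0.08)


class TestEllipticity:
    def test_isotropic_sphere_scores_one(self, rng):
        v = rng.normal(size=(10_000, 3))
        pts = v / np.linalg.norm(v, axis=1, keepdims=True)
        assert metrics.ellipticity_score(pts) == pytest.approx(1.0, abs=0.05)

    def test_two_to_one_ellipsoid_recovered(self, rng):
        v = rng.normal(size=(10_000, 3))
        sphere = v / np.linalg.norm(v, axis=1, keepdims=True)
        pts = sphere * [2.0, 1.0, 1.0]
        R = Rotation.from_euler("xyz", [10, 70, 35], degrees=True).as_matrix()
        assert metrics.ellipticity_score(pts @ R.T) == pytest.approx(2.0, rel=0.05)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            metrics.ellipticity_score(np.eye(3))

    def test_ratio_identity_and_symmetry(self):
        assert metrics.ellipticity_ratio(1.7, 1.7) == 1.0
        assert metrics.ellipticity_ratio(2.0, 1.0) == 2.0
        assert metrics.ellipticity_ratio(1.3, 2.6) == metrics.ellipticity_ratio(2.6, 1.3)

    @given(st.floats(1.0, 10.0), st.floats(1.0, 10.0))
    @settings(max_examples=50, derandomize=True)
    def test_ratio_at_least_one(self, a, b):
        r = metrics.ellipticity_ratio(a, b)
        assert r >= 1.0
        assert (r == 1.0) == (a == b)

    def test_ratio_domain(self):
        with pytest.raises(ValueError):
            metrics.ellipticity_ratio(0.9, 1.5)


class TestRandomPairNull:
    def test_identical_scores_give_unit_ratios(self):
        null, _ = metrics.random_pair_null(np.full(10, 1.4), n_pairs=100, seed=0)
        np.testing.assert_array_equal(null, 1.0)

    def test_deterministic_given_seed(self, rng):
        scores = 1.0 + rng.lognormal(sigma=0.5, size=20)
        a, _ = metrics.random_pair_null(scores, n_pairs=500, seed=42)
        b, _ = metrics.random_pair_null(scores, n_pairs=500, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_detects_planted_within_nucleus_effect(self, rng):
        scores = 1.0 + rng.lognormal(sigma=0.5, size=38)
        null, _ = metrics.random_pair_null(scores, n_pairs=1000, seed=1)
        within = 2.0 * null[rng.integers(0, len(null), 19)]
        _, test = metrics.random_pair_null(scores, n_pairs=1000, seed=2,
                                           within_ratios=within)
        assert test.pvalue < 0.01

    def test_too_few_scores(self):
        with pytest.raises(ValueError):
            metrics.random_pair_null(np.array([1.0, 1.2, 1.5]))


class TestPcaClassify:
    @staticmethod
    def feature_frame(X):
        import pandas as pd
        return pd.DataFrame(X, columns=metrics.FEATURE_COLUMNS)

    def test_planted_clusters_recovered(self, rng):
        n = 200
        X = rng.normal(size=(2 * n, 19))
        X[n:, 10] += 6.0  # volume_z column separated by 6 sigma
        feats = self.feature_frame(X)
        _, _, labels = metrics.pca_classify(feats)
        planted = np.r_[np.full(n, 2), np.full(n, 1)]  # shifted group: larger volume
        acc = max((labels == planted).mean(), (labels == (3 - planted)).mean())
        assert acc >= 0.95
        # cluster 1 is the larger-volume group by convention
        assert feats["volume_z"][labels == 1].mean() > feats["volume_z"][labels == 2].mean()

    def test_duplicating_rows_keeps_directions(self, rng):
        X = rng.normal(size=(100, 19))
        f1 = self.feature_frame(X)
        f2 = self.feature_frame(np.vstack([X, X]))
        s1, evr1, _ = metrics.pca_classify(f1)
        s2, evr2, _ = metrics.pca_classify(f2)
        np.testing.assert_allclose(evr1, evr2, atol=1e-9)
        np.testing.assert_allclose(np.abs(s2[:100]), np.abs(s1), atol=1e-8)

    def test_missing_values_rejected(self, rng):
        X = rng.normal(size=(50, 19))
        X[3, 4] = np.nan
        with pytest.raises(ValueError):
            metrics.pca_classify(self.feature_frame(X))


class TestCompartmentProfile:
    @pytest.mark.parametrize("h1, h2, want", [
        (np.ones(9), np.ones(9), np.ones(9)),
        (np.ones(9), np.full(9, 2), np.zeros(9)),
        (np.full(9, 2), np.full(9, 2), np.full(9, -1)),
    ])
    def test_printed_cases(self, h1, h2, want):
        np.testing.assert_array_equal(metrics.compartment_profile(h1, h2), want)

    def test_mixed_vector(self):
        h1 = np.array([1, 1, 2, 2, 1, 2, 1, 2, 1])
        h2 = np.array([1, 2, 2, 1, 1, 2, 2, 2, 1])
        want = np.array([1, 0, -1, 0, 1, -1, 0, -1, 1])
        np.testing.assert_array_equal(metrics.compartment_profile(h1, h2), want)

    def test_wrong_length(self):
        with pytest.raises(ValueError):
            metrics.compartment_profile(np.ones(8), np.ones(8))


class TestPairwiseMatrices:
    def test_symmetry_and_diagonals(self, rng):
        maps = [blob_map(c, rng, n=250) for c in
                ([0, 0, 0], [300, 0, 0], [0, 350, 0])]
        ds, es = metrics.pairwise_matrices(maps)
        np.testing.assert_allclose(ds, ds.T)
        np.testing.assert_allclose(es, es.T)
        np.testing.assert_allclose(np.diag(ds), 0.0)
        np.testing.assert_allclose(np.diag(es), 1.0)
        assert (es >= 0).all() and (es <= 1).all()
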