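import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from synaptoscope.clustergeom import (
    axial_projection,
    binned_profile,
    center_of_mass,
    cluster_diameter,
    detect_cord_clusters,
    fraction_within,
    profile_pair,
)


class TestCenterOfMass:
    def test_two_points(self):
        np.testing.assert_allclose(center_of_mass([(0, 0), (2, 0)]), (1, 0))

    def test_single_point(self):
        np.testing.assert_allclose(center_of_mass([(3.5, -1.2)]), (3.5, -1.2))

    def test_matches_direct_sum(self, rng):
        pts = rng.uniform(-1, 1, (100, 2))
        expected = np.array([sum(p[0] for p in pts), sum(p[1] for p in pts)]) / 100
        np.testing.assert_allclose(center_of_mass(pts), expected, atol=1e-9)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            center_of_mass(np.empty((0, 2)))


class TestAxialProjection:
    def test_origin_and_target_centers(self, rng):
        origin = rng.normal((0, 0), 5, (200, 2))
        target = rng.normal((500, 0), 5, (200, 2))
        oax, tax = axial_projection(origin, target)
        d = np.linalg.norm(center_of_mass(target) - center_of_mass(origin))
        assert oax.mean() == pytest.approx(0, abs=1e-9)
        assert tax.mean() == pytest.approx(d, abs=1e-9)

    def test_rotation_invariance(self, rng):
        origin = rng.normal((0, 0), 50, (300, 2))
        target = rng.normal((400, 120), 60, (300, 2))
        oax, tax = axial_projection(origin, target)
        th = 1.234
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        oax2, tax2 = axial_projection(origin @ R.T, target @ R.T)
        np.testing.assert_allclose(oax, oax2, atol=1e-8)
        np.testing.assert_allclose(tax, tax2, atol=1e-8)

    def test_translation_invariance(self, rng):
        origin = rng.normal((0, 0), 50, (100, 2))
        target = rng.normal((300, 0), 50, (100, 2))
        oax, tax = axial_projection(origin, target)
        shift = np.array([123.4, -56.7])
        oax2, tax2 = axial_projection(origin + shift, target + shift)
        np.testing.assert_allclose(oax, oax2, atol=1e-8)
        np.testing.assert_allclose(tax, tax2, atol=1e-8)

    def test_swap_negates_and_shifts(self, rng):
        origin = rng.normal((0, 0), 50, (100, 2))
        target = rng.normal((300, 0), 50, (100, 2))
        oax, tax = axial_projection(origin, target)
        tax_s, oax_s = axial_projection(target, origin)
        d = np.linalg.norm(center_of_mass(target) - center_of_mass(origin))
        # swapping origin and target reverses the axis: x -> d - x
        np.testing.assert_allclose(oax_s, d - oax, atol=1e-8)
        np.testing.assert_allclose(tax_s, d - tax, atol=1e-8)

    def test_coincident_centers_error(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="axis"):
            axial_projection(pts, pts)


class TestBinnedProfile:
    def test_single_bin(self):
        edges, fr = binned_profile(np.zeros(10))
        assert fr.tolist() == [1.0]
        assert edges[0] == 0.0

    def test_half_open_boundary(self):
        edges, fr = binned_profile(np.array([0.0, 33.0]))
        np.testing.assert_allclose(fr, [0.5, 0.5])
        np.testing.assert_allclose(edges[:2], [0.0, 33.0])

    def test_matches_gaussian_cdf(self, rng):
        x = rng.normal(0, 50, 10_000)
        edges, fr = binned_profile(x)
        expected = np.diff(stats.norm.cdf(edges, 0, 50))
        np.testing.assert_allclose(fr, expected, atol=0.01)

    @settings(deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            st.integers(1, 200),
            elements=st.floats(-1e4, 1e4, allow_nan=False),
        )
    )
    def test_fractions_sum_to_one(self, x):
        _, fr = binned_profile(x)
        assert fr.sum() == pytest.approx(1.0)


class TestClusterDiameter:
    def test_uniform_interval(self, rng):
        x = rng.uniform(-50, 50, 100_000)
        assert cluster_diameter(x) == pytest.approx(95.0, abs=0.5)

    def test_gaussian_matches_quantile_width(self, rng):
        x = rng.normal(0, 75, 100_000)
        expected = 2 * stats.norm.ppf(0.975) * 75  # 3.92 sigma ~ 294 nm
        assert cluster_diameter(x) == pytest.approx(expected, rel=0.01)

    def test_identical_points_zero(self):
        assert cluster_diameter(np.full(5, 3.3)) == 0.0

    def test_scale_equivariance(self, rng):
        x = rng.normal(0, 10, 5000)
        assert cluster_diameter(3 * x) == pytest.approx(3 * cluster_diameter(x))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cluster_diameter(np.array([1.0]))


class TestFractionWithin:
    def test_self_interval_captures_95_percent(self, rng):
        x = rng.normal(0, 75, 50_000)
        lo, hi = np.percentile(x, [2.5, 97.5])
        assert fraction_within(x, (lo, hi)) == pytest.approx(0.95, abs=0.005)

    def test_disjoint_clusters(self, rng):
        assert fraction_within(rng.normal(1000, 10, 100), (-50, 50)) == 0.0

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            fraction_within(np.array([0.0]), (5, 5))


class TestProfilePair:
    def test_recovers_planted_offset_and_diameter(self, rng):
        # two Gaussian clusters: offset 124 nm, per-axis spread 75 nm
        origin = rng.normal((0, 0), 75, (4000, 2))
        target = rng.normal((124, 0), 75, (4000, 2))
        po, pt = profile_pair(origin, target, "ELKS", "CaV2")
        offset = pt.axial.mean() - po.axial.mean()
        assert offset == pytest.approx(124, abs=3 * 75 / np.sqrt(4000) * np.sqrt(2))
        expected_diam = 2 * stats.norm.ppf(0.975) * 75
        assert po.diameter == pytest.approx(expected_diam, rel=0.05)
        assert pt.diameter == pytest.approx(expected_diam, rel=0.05)


class TestDetectCordClusters:
    @staticmethod
    def _cord(rng, spacings_nm, n_per=100, sigma=50.0):
        centers = np.concatenate([[0.0], np.cumsum(spacings_nm)])
        pts = np.concatenate(
            [rng.normal((c, 0), sigma, (n_per, 2)) for c in centers]
        )
        return pts, centers

    def test_planted_regular_spacing(self, rng):
        pts, centers = self._cord(rng, [1000.0] * 9)
        res = detect_cord_clusters(pts)
        assert res.n_clusters == 10
        np.testing.assert_allclose(res.spacings, 1000, atol=25)
        assert res.clusters_per_um == pytest.approx(1.0, rel=0.15)

    def test_single_cluster_flagged(self, rng):
        pts = rng.normal((0, 0), 50, (100, 2))
        with pytest.warns(UserWarning):
            res = detect_cord_clusters(pts)
        assert res.n_clusters == 1
        assert np.isnan(res.clusters_per_um)

    def test_spacing_parameter_recovery(self):
        rng = np.random.default_rng(99)
        means = []
        for _ in range(50):
            gaps = rng.normal(1100, 160, 9).clip(700)
            pts, _ = self._cord(rng, gaps, n_per=60)
            res = detect_cord_clusters(pts)
            if res.n_clusters >= 2:
                means.append(res.spacings.mean())
        assert np.mean(means) == pytest.approx(1100, abs=30)
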