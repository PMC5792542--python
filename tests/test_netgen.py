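"""Spatial network generation: kernel weights, preference, density, assortment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psinet import netgen


def brute_force_weights(points, r):
    """All-pairs double loop evaluation of the distance kernel."""
    n = len(points)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j or r == 0:
                continue
            d2 = (points[i][0] - points[j][0]) ** 2 + (points[i][1] - points[j][1]) ** 2
            w[i, j] = np.exp(-d2 / r)
    return w


def brute_force_assortativity(w, x):
    """Directed-edge-end evaluation of the weighted assortativity formula."""
    n = len(x)
    total = sxy = sx = sxx = 0.0
    for i in range(n):
        for j in range(n):
            total += w[i, j]
            sxy += w[i, j] * x[i] * x[j]
            sx += w[i, j] * x[i]
            sxx += w[i, j] * x[i] ** 2
    if total == 0:
        return float("nan")
    xbar = sx / total
    den = sxx / total - xbar**2
    if den <= 0:
        return float("nan")
    return (sxy / total - xbar**2) / den


class TestPositions:
    def test_uniform_in_unit_square(self, rng):
        pts = netgen.sample_positions(50, rng)
        assert pts.shape == (50, 2)
        assert np.all((pts >= 0) & (pts <= 1))

    def test_minimal_group(self, rng):
        assert netgen.sample_positions(2, rng).shape == (2, 2)

    def test_rejects_singleton(self, rng):
        with pytest.raises(ValueError):
            netgen.sample_positions(1, rng)

    def test_coordinate_means_converge_to_half(self, rng):
        pts = netgen.sample_positions(100_000, rng)
        se = np.sqrt(1.0 / 12.0 / 100_000)
        assert np.all(np.abs(pts.mean(axis=0) - 0.5) < 3 * se)


class TestAttraction:
    def test_two_points_move_toward_each_other(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        out = netgen.attract_to_nearest(pts, 0.15)
        np.testing.assert_allclose(out, [[0.15, 0.0], [0.85, 0.0]])

    def test_zero_fraction_is_identity(self, rng):
        pts = netgen.sample_positions(10, rng)
        np.testing.assert_array_equal(netgen.attract_to_nearest(pts, 0.0), pts)

    def test_collinear_synchronous_move(self):
        # nearest neighbours on the INPUT configuration: 0 -> 0.4, 0.4 -> 0,
        # 1.0 -> 0.4; all move simultaneously by 15% of the gap
        pts = np.array([[0.0, 0.0], [0.4, 0.0], [1.0, 0.0]])
        out = netgen.attract_to_nearest(pts, 0.15)
        np.testing.assert_allclose(out[:, 0], [0.06, 0.34, 0.91])

    def test_nearest_neighbour_matches_all_pairs_scan(self, rng):
        pts = netgen.sample_positions(20, rng)
        out = netgen.attract_to_nearest(pts, 0.15)
        for i in range(20):
            d = [np.inf if j == i else np.linalg.norm(pts[i] - pts[j]) for j in range(20)]
            nn = int(np.argmin(d))
            np.testing.assert_allclose(out[i], pts[i] + 0.15 * (pts[nn] - pts[i]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_stays_in_unit_square(self, seed):
        pts = netgen.sample_positions(12, np.random.default_rng(seed))
        out = netgen.attract_to_nearest(pts, 0.15)
        assert np.all((out >= 0) & (out <= 1))

    def test_invalid_fraction(self, rng):
        with pytest.raises(ValueError):
            netgen.attract_to_nearest(netgen.sample_positions(3, rng), 1.0)


class TestBaseWeights:
    def test_kernel_value_at_half_distance(self):
        pts = np.array([[0.0, 0.0], [0.5, 0.0]])
        w = netgen.base_weights(pts, 1.0)
        np.testing.assert_allclose(w[0, 1], np.exp(-0.25))

    def test_coincident_points_fully_connected(self):
        w = netgen.base_weights(np.zeros((2, 2)), 0.5)
        assert w[0, 1] == 1.0

    def test_zero_range_gives_empty_network(self, rng):
        w = netgen.base_weights(netgen.sample_positions(8, rng), 0.0)
        assert np.all(w == 0)

    def test_negative_range_rejected(self, rng):
        with pytest.raises(ValueError):
            netgen.base_weights(netgen.sample_positions(3, rng), -0.1)

    def test_symmetric_zero_diagonal_and_matches_brute_force(self, rng):
        for _ in range(10):
            pts = netgen.sample_positions(6, rng)
            r = rng.uniform(0.05, 3.0)
            w = netgen.base_weights(pts, r)
            np.testing.assert_array_equal(w, w.T)
            assert np.all(np.diag(w) == 0)
            np.testing.assert_allclose(w, brute_force_weights(pts, r), rtol=1e-12)


class TestSimilarityMultiplier:
    def test_none_mode_is_identity(self):
        assert float(netgen.similarity_multiplier(0.7, 0.2, "none")) == 1.0

    def test_midpoint_logistic_value(self):
        # logistic is exactly 1/2 at the midpoint difference 0.5
        m = netgen.similarity_multiplier(0.5, 0.2, "homophily")
        np.testing.assert_allclose(float(m), 0.6)

    def test_identical_individuals_under_heterophily(self):
        m = netgen.similarity_multiplier(0.0, 0.2, "heterophily")
        np.testing.assert_allclose(float(m), 0.5 - 0.2 / (1 + np.exp(-10)), rtol=1e-12)

    @pytest.mark.parametrize("mode,sign", [("homophily", 1), ("heterophily", -1)])
    def test_range_bounds(self, mode, sign):
        d = np.linspace(0, 2, 101)
        m = netgen.similarity_multiplier(d, 0.2, mode)
        assert np.all(m >= 0.5 - 0.2 - 1e-12) and np.all(m <= 0.5 + 0.2 + 1e-12)
        # similar pairs are favoured under homophily, penalized under heterophily
        assert sign * (m[0] - m[-1]) > 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            netgen.similarity_multiplier(0.1, 0.7, "homophily")
        with pytest.raises(ValueError):
            netgen.similarity_multiplier(0.1, 0.2, "sociophily")


class TestApplySimilarity:
    def test_none_mode_unchanged(self, rng):
        w = netgen.base_weights(netgen.sample_positions(5, rng), 1.0)
        np.testing.assert_array_equal(netgen.apply_similarity(w, np.zeros(5), 0.2, "none"), w)

    def test_identical_traits_homophily_value(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = netgen.apply_similarity(w, np.array([0.3, 0.3]), 0.2, "homophily")
        np.testing.assert_allclose(out[0, 1], 0.5 + 0.2 / (1 + np.exp(-10)), rtol=1e-12)
        np.testing.assert_allclose(out[0, 1], 0.700, atol=5e-4)

    @pytest.mark.parametrize("mode", ["homophily", "heterophily"])
    def test_symmetry_preserved(self, rng, mode):
        w = netgen.base_weights(netgen.sample_positions(7, rng), 0.8)
        out = netgen.apply_similarity(w, rng.uniform(-1, 1, 7), 0.15, mode)
        np.testing.assert_array_equal(out, out.T)
        assert np.all(np.diag(out) == 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            netgen.apply_similarity(np.zeros((3, 3)), np.zeros(4), 0.1, "homophily")


class TestThreshold:
    @pytest.mark.parametrize(
        "value,expected", [(0.049, 0.0), (0.05, 0.05), (0.51, 0.51)]
    )
    def test_strictly_below_cutoff_removed(self, value, expected):
        w = np.array([[0.0, value], [value, 0.0]])
        assert netgen.threshold_weights(w, 0.05)[0, 1] == expected

    def test_zero_cutoff_identity(self, rng):
        w = netgen.base_weights(netgen.sample_positions(5, rng), 0.5)
        np.testing.assert_array_equal(netgen.threshold_weights(w, 0.0), w)


class TestDensity:
    def test_fully_connected(self):
        w = np.ones((3, 3)) - np.eye(3)
        assert netgen.network_density(w) == 1.0

    def test_partial_weights(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        np.testing.assert_allclose(netgen.network_density(w), 0.5 / 3)

    def test_empty_matrix(self):
        assert netgen.network_density(np.zeros((4, 4))) == 0.0

    def test_degenerate_network_rejected(self):
        with pytest.raises(ValueError):
            netgen.network_density(np.zeros((1, 1)))

    def test_monotone_nondecreasing_in_r(self, rng):
        pts = netgen.attract_to_nearest(netgen.sample_positions(30, rng), 0.15)
        dens = [
            netgen.network_density(
                netgen.threshold_weights(netgen.base_weights(pts, r), 0.05)
            )
            for r in [0.0, 0.02, 0.1, 0.5, 1.0, 3.0, 9.0]
        ]
        assert all(b >= a for a, b in zip(dens, dens[1:]))


class TestAssortativity:
    def test_perfect_assortment(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        assert netgen.weighted_assortativity(w, [1, 1, -1, -1]) == pytest.approx(1.0)

    def test_perfect_disassortment(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        assert netgen.weighted_assortativity(w, [1, -1, 1, -1]) == pytest.approx(-1.0)

    def test_path_matches_directed_edge_oracle(self):
        w = np.zeros((4, 4))
        for i in range(3):
            w[i, i + 1] = w[i + 1, i] = 1.0
        x = np.array([0.0, 1.0, 0.0, 1.0])
        np.testing.assert_allclose(
            netgen.weighted_assortativity(w, x), brute_force_assortativity(w, x)
        )

    def test_random_weighted_instances_match_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 7))
            w = rng.uniform(0, 1, (n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            x = rng.normal(size=n)
            np.testing.assert_allclose(
                netgen.weighted_assortativity(w, x),
                brute_force_assortativity(w, x),
                rtol=1e-10,
            )

    def test_undefined_on_empty_or_constant(self):
        assert np.isnan(netgen.weighted_assortativity(np.zeros((3, 3)), [1, 2, 3]))
        w = np.ones((3, 3)) - np.eye(3)
        assert np.isnan(netgen.weighted_assortativity(w, [2.0, 2.0, 2.0]))

    def test_bounded_on_random_networks(self, rng):
        for _ in range(20):
            w = rng.uniform(0, 1, (8, 8))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            rho = netgen.weighted_assortativity(w, rng.normal(size=8))
            assert -1 - 1e-9 <= rho <= 1 + 1e-9

    def test_homophily_raises_assortment_on_average(self):
        # directional: preference for similar partners yields higher
        # measured trait assortment than the untouched base network
        diffs = []
        for rep in range(50):
            r = np.random.default_rng(1000 + rep)
            pts = netgen.attract_to_nearest(netgen.sample_positions(30, r), 0.15)
            traits = r.uniform(-1, 1, 30)
            base = netgen.threshold_weights(netgen.base_weights(pts, 0.9), 0.05)
            homo = netgen.threshold_weights(
                netgen.apply_similarity(
                    netgen.base_weights(pts, 0.9), traits, 0.2, "homophily"
                ),
                0.05,
            )
            diffs.append(
                netgen.weighted_assortativity(homo, traits)
                - netgen.weighted_assortativity(base, traits)
            )
        assert np.nanmean(diffs) > 0
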