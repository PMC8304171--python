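"""Nearest-neighbour spatial entropy and the reference pattern generators."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from courtentropy import (
    LATTICE_CEILING,
    CourtGeometry,
    PointPattern,
    expected_random_nn,
    generate_clustered_pattern,
    generate_lattice_pattern,
    generate_random_pattern,
    mean_nn_distance,
    nn_distance_density,
    spatial_entropy,
)
from courtentropy.errors import InsufficientPointsError, InvalidInputError


def brute_force_mean_nn(points):
    """O(N^2) all-pairs nearest-neighbour mean."""
    pts = np.asarray(points)
    n = len(pts)
    total = 0.0
    for i in range(n):
        best = math.inf
        for j in range(n):
            if i != j:
                d = math.hypot(*(pts[i] - pts[j]))
                best = min(best, d)
        total += best
    return total / n


class TestMeanNNDistance:
    def test_two_points(self):
        pat = PointPattern(points=np.array([[0.0, 0.0], [0.0, 3.0]]), window_area=10.0)
        assert mean_nn_distance(pat) == pytest.approx(3.0)

    def test_collinear_hand_computation(self):
        pat = PointPattern(points=np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]]), window_area=10.0)
        assert mean_nn_distance(pat) == pytest.approx(4.0 / 3.0)

    def test_unit_square_corners(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        pat = PointPattern(points=pts, window_area=1.0)
        assert mean_nn_distance(pat) == pytest.approx(1.0)
        assert spatial_entropy(pat).Hs == pytest.approx(4.0)  # 1.0 / 0.25

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(InsufficientPointsError):
            mean_nn_distance(PointPattern(points=np.array([[0.0, 0.0]]), window_area=1.0))

    def test_duplicates_contribute_zero(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [4.0, 1.0]])
        pat = PointPattern(points=pts, window_area=10.0)
        assert mean_nn_distance(pat) == pytest.approx(1.0)  # (0 + 0 + 3)/3

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for n in (10, 100, 500):
            pts = rng.random((n, 2)) * [5.18, 6.7]
            pat = PointPattern(points=pts, window_area=34.706)
            assert mean_nn_distance(pat) == pytest.approx(brute_force_mean_nn(pts), abs=1e-12)


class TestRandomExpectation:
    @pytest.mark.parametrize(
        "S, N, expect",
        [(1.0, 4, 0.25), (100.0, 25, 1.0), (5.18 * 6.7, 500, 0.5 * math.sqrt(5.18 * 6.7 / 500))],
    )
    def test_formula(self, S, N, expect):
        assert expected_random_nn(S, N) == pytest.approx(expect, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            expected_random_nn(-1.0, 10)
        with pytest.raises(InvalidInputError):
            expected_random_nn(1.0, 0)

    def test_poisson_nn_density_normalizes_and_matches_mean(self):
        delta = 500 / 34.706
        assert nn_distance_density(0.0, delta) == 0.0
        total, _ = quad(lambda r: nn_distance_density(r, delta), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)
        mean, _ = quad(lambda r: r * nn_distance_density(r, delta), 0, np.inf)
        assert mean == pytest.approx(1.0 / (2.0 * math.sqrt(delta)), rel=1e-9)
        # consistency with the Clark-Evans expectation at S = N/delta
        assert mean == pytest.approx(expected_random_nn(500 / delta, 500), rel=1e-9)
        with pytest.raises(InvalidInputError):
            nn_distance_density(-0.1, delta)


class TestSpatialEntropyInvariances:
    def test_rigid_motion_and_rescale(self):
        rng = np.random.default_rng(11)
        pts = rng.random((200, 2)) * [5.18, 6.7]
        pat = PointPattern(points=pts, window_area=34.706)
        h0 = spatial_entropy(pat).Hs
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        moved = pts @ rot.T + [10.0, -3.0]
        assert spatial_entropy(PointPattern(points=moved, window_area=34.706)).Hs == pytest.approx(
            h0, rel=1e-12
        )
        scaled = PointPattern(points=pts * 2.5, window_area=34.706 * 2.5**2)
        assert spatial_entropy(scaled).Hs == pytest.approx(h0, rel=1e-12)


class TestGenerators:
    def test_random_pattern_deterministic_and_uniform(self, geom):
        a = generate_random_pattern(500, geom, seed=9)
        b = generate_random_pattern(500, geom, seed=9)
        assert np.array_equal(a.points, b.points)
        assert not np.array_equal(a.points, generate_random_pattern(500, geom, seed=10).points)
        # uniform moments: x-mean within 3 sigma of width/2
        sigma = geom.width / math.sqrt(12) / math.sqrt(500)
        assert abs(a.points[:, 0].mean() - geom.width / 2) < 3 * sigma

    def test_random_pattern_baseline_near_one(self, geom):
        vals = [spatial_entropy(generate_random_pattern(500, geom, seed=s)).Hs for s in range(100)]
        assert 0.95 < np.mean(vals) < 1.05

    def test_lattice_count_spacing_and_ceiling(self, geom):
        pat = generate_lattice_pattern(1000, geom)
        assert 900 <= pat.n <= 1100  # within 10% of target
        # every point's NN distance equals the lattice spacing
        from scipy.spatial import cKDTree

        d = cKDTree(pat.points).query(pat.points, k=2)[0][:, 1]
        assert np.ptp(d) < 1e-9
        hs = spatial_entropy(pat).Hs
        assert 1.9 < hs <= LATTICE_CEILING
        # doubling the target shrinks the NN spacing by sqrt(2)
        d2 = mean_nn_distance(generate_lattice_pattern(2000, geom))
        assert d.mean() / d2 == pytest.approx(math.sqrt(2.0), rel=0.02)

    def test_lattice_ceiling_constant(self):
        assert LATTICE_CEILING == pytest.approx(2.149, abs=5e-4)

    def test_clustered_entropy_below_one_and_monotone_in_spread(self, geom):
        means = []
        for spread in (0.1, 0.4, 1.0):
            vals = [
                spatial_entropy(
                    generate_clustered_pattern(500, spread=spread, geom=geom, seed=s)
                ).Hs
                for s in range(50)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
        assert means[1] < 1.0  # corner clusters at 0.4 m are clearly clustered

    def test_clustered_shrinking_spread_drives_entropy_to_zero(self, geom):
        vals = [
            spatial_entropy(
                generate_clustered_pattern(400, spread=s, geom=geom, seed=1)
            ).Hs
            for s in (0.2, 0.02, 0.002)
        ]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 0.01
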