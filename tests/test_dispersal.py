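"""Dispersal kernel construction, seed redistribution and recruitment."""

from __future__ import annotations

import math

import numpy as np
import pytest

from thermarange import ValueParseError, build_kernel, disperse, recruit


def scatter_oracle(seeds: np.ndarray, kernel) -> np.ndarray:
    """Brute-force per-cell scatter loop with absorbing edges."""
    rows, cols = seeds.shape
    R = kernel.radius
    arrivals = np.zeros_like(seeds)
    for i in range(rows):
        for j in range(cols):
            if seeds[i, j] == 0:
                continue
            for di in range(-R, R + 1):
                for dj in range(-R, R + 1):
                    ti, tj = i + di, j + dj
                    if 0 <= ti < rows and 0 <= tj < cols:
                        arrivals[ti, tj] += seeds[i, j] * kernel.weights[R + di, R + dj]
    return arrivals


class TestKernel:
    def test_weights_normalised_and_centre_dominates(self):
        for mean, mx in [(0.5, 1), (2.0, 2), (1.0, 5), (3.0, 9)]:
            kernel = build_kernel(mean, mx)
            assert kernel.weights.sum() == pytest.approx(1.0, abs=1e-12)
            centre = kernel.weights[kernel.radius, kernel.radius]
            assert centre == kernel.weights.max()

    def test_isotropy_under_rotation_and_reflection(self):
        kernel = build_kernel(2.0, 3)
        np.testing.assert_array_equal(kernel.weights, np.rot90(kernel.weights))
        np.testing.assert_array_equal(kernel.weights, np.fliplr(kernel.weights))

    def test_tiny_mean_distance_retains_all_seeds(self):
        # orchid-like traits: mean 0.0005 cells, max 1 cell
        kernel = build_kernel(0.0005, 1)
        assert kernel.weights[kernel.radius, kernel.radius] > 1 - 1e-6

    def test_five_by_five_window_distances(self):
        kernel = build_kernel(2.0, 2)  # alpha = 1
        w = kernel.weights
        assert w.shape == (5, 5)
        assert w[0, 0] == 0.0  # corner at distance 2*sqrt(2) > 2, truncated
        centre = w[2, 2]
        assert w[2, 3] / centre == pytest.approx(math.exp(-1.0), rel=1e-12)
        assert w[1, 3] / centre == pytest.approx(math.exp(-math.sqrt(2)), rel=1e-12)

    @pytest.mark.parametrize(("mean", "mx"), [(1.0, 0), (0.0, 1), (-1.0, 2)])
    def test_invalid_traits_rejected(self, mean, mx):
        with pytest.raises(ValueParseError):
            build_kernel(mean, mx)

    def test_sampled_mean_distance_matches_trait(self):
        """Sampling displacements from the continuous kernel recovers a mean
        distance close to the species trait when truncation is mild."""
        mean_trait = 2.0
        kernel = build_kernel(mean_trait, 30)
        R = kernel.radius
        offsets = np.arange(-R, R + 1)
        dist = np.hypot(offsets[:, None], offsets[None, :])
        realised = (kernel.weights * dist).sum()
        assert realised == pytest.approx(mean_trait, rel=0.15)


class TestDisperse:
    def test_interior_source_conserves_mass(self):
        seeds = np.zeros((9, 9))
        seeds[4, 4] = 100.0
        arrivals = disperse(seeds, build_kernel(2.0, 2))
        assert arrivals.sum() == pytest.approx(100.0, abs=1e-9)

    def test_corner_source_loses_mass_over_the_edge(self):
        seeds = np.zeros((9, 9))
        seeds[0, 0] = 100.0
        arrivals = disperse(seeds, build_kernel(2.0, 2))
        assert arrivals.sum() < 100.0

    def test_matches_brute_force_scatter(self):
        rng = np.random.default_rng(11)
        kernel = build_kernel(1.5, 3)
        for _ in range(3):
            seeds = rng.random((9, 9)) * 50
            np.testing.assert_allclose(
                disperse(seeds, kernel), scatter_oracle(seeds, kernel), atol=1e-9
            )

    def test_linearity(self):
        rng = np.random.default_rng(5)
        kernel = build_kernel(2.0, 2)
        a, b = rng.random((6, 6)), rng.random((6, 6))
        np.testing.assert_allclose(
            disperse(a + b, kernel),
            disperse(a, kernel) + disperse(b, kernel),
            atol=1e-12,
        )

    def test_buffer_rim_eliminates_edge_loss(self):
        kernel = build_kernel(2.0, 2)
        seeds = np.zeros((10, 10))
        seeds[2:8, 2:8] = 7.0  # rim of width 2 = kernel radius
        assert disperse(seeds, kernel).sum() == pytest.approx(seeds.sum(), abs=1e-9)


class TestRecruit:
    def test_deterministic_floors(self):
        out = recruit(np.array([[2.7, 0.2], [5.0, 0.0]]), stochastic=False)
        np.testing.assert_array_equal(out, [[2, 0], [5, 0]])
        assert out.dtype == np.int64

    def test_zero_intensity_is_always_zero(self):
        rng = np.random.default_rng(3)
        out = recruit(np.zeros((4, 4)), stochastic=True, rng=rng)
        assert np.all(out == 0)

    def test_poisson_mean_matches_intensity(self):
        rng = np.random.default_rng(123)
        draws = recruit(np.full((100_000,), 4.0), stochastic=True, rng=rng)
        se = math.sqrt(4.0 / 100_000)
        assert abs(draws.mean() - 4.0) < 3 * se

    def test_expected_recruits_equal_deterministic_intensity_field(self):
        rng = np.random.default_rng(9)
        lam = np.array([[0.5, 2.0], [4.0, 8.0]])
        total = np.zeros_like(lam)
        n = 20_000
        for _ in range(n):
            total += recruit(lam, stochastic=True, rng=rng)
        np.testing.assert_allclose(total / n, lam, atol=4 * math.sqrt(8.0 / n))

    def test_seeded_draws_reproducible(self):
        lam = np.random.default_rng(0).random((5, 5)) * 3
        a = recruit(lam, stochastic=True, rng=np.random.default_rng(42))
        b = recruit(lam, stochastic=True, rng=np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)
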