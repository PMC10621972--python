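"""Direction sampling, natural coordinates, shape functions and interpolation."""

import numpy as np
import pytest
from scipy import stats

from conftest import random_rotation
from efdangio import (
    EFD,
    InvalidParameterError,
    OutOfDomainError,
    RandomEngine,
    build_icosphere,
    geodesic_interpolate,
    histogram_from_directions,
    interpolation_weights,
    natural_coordinates,
    sample_direction,
    sample_directions,
    vector_interpolate,
)


class TestSampleDirection:
    def test_unit_norm(self, rng):
        d = sample_directions(EFD(np.diag([5.0, 1, 0.5])), 1000, rng)
        assert np.abs(np.linalg.norm(d, axis=1) - 1.0).max() < 1e-12

    def test_isotropic_acceptance_rate(self, rng):
        n = 10**5
        _, info = sample_directions(EFD(np.eye(3)), n, rng, return_stats=True)
        rate = info["accepted"] / info["proposals"]
        p = np.pi / 6.0
        sd = np.sqrt(p * (1 - p) / info["proposals"])
        assert abs(rate - p) < 4 * sd

    def test_isotropic_uniformity_chi_square(self, mesh2, rng):
        from conftest import voronoi_props

        d = sample_directions(EFD(np.eye(3)), 10**5, rng)
        h = histogram_from_directions(d, mesh2)
        counts = h.mass * len(d)
        expected = len(d) * voronoi_props(mesh2)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=mesh2.n_facets - 1) > 0.01

    def test_modal_facet_contains_major_axis(self, mesh2, rng):
        d = sample_directions(EFD(np.diag([5.0, 1, 1])), 10**5, rng)
        h = histogram_from_directions(d, mesh2, symmetrize=True)
        hot = mesh2.facet_centroids[np.argmax(h.mass)]
        assert abs(hot[0]) > 0.95

    def test_rotation_equivariance_two_sample(self, mesh2, rng):
        # samples from R P R^T should match R applied to samples from P
        P = np.diag([4.0, 1.5, 0.7])
        R = random_rotation(np.random.default_rng(7))
        n = 4 * 10**4
        d1 = sample_directions(EFD(P), n, rng) @ R.T
        d2 = sample_directions(EFD(R @ P @ R.T), n, rng)
        h1 = histogram_from_directions(d1, mesh2).mass * n
        h2 = histogram_from_directions(d2, mesh2).mass * n
        keep = (h1 + h2) > 10
        chi2 = ((h1[keep] - h2[keep]) ** 2 / (h1[keep] + h2[keep])).sum()
        assert stats.chi2.sf(chi2, df=keep.sum() - 1) > 0.01

    def test_sampler_density_follows_radius_cubed(self, rng):
        # brute-force oracle: for radii (2,1,1), P(|x-component| > cos 45deg)
        # under density ~ rho(u)^3 integrated numerically
        mesh = build_icosphere(4)
        P = EFD(np.diag([2.0, 1.0, 1.0]))
        rho = 1.0 / np.linalg.norm(mesh.vertices @ np.diag([1 / 2.0, 1, 1]), axis=1)
        w = mesh.vertex_areas * rho**3
        w /= w.sum()
        target = w[np.abs(mesh.vertices[:, 0]) > np.sqrt(0.5)].sum()
        d = sample_directions(P, 10**5, rng)
        frac = np.mean(np.abs(d[:, 0]) > np.sqrt(0.5))
        assert frac == pytest.approx(target, abs=0.01)

    def test_single_draw(self, rng):
        d = sample_direction(EFD(np.eye(3)), rng)
        assert d.shape == (3,)
        assert np.linalg.norm(d) == pytest.approx(1.0)


class TestRandomEngine:
    def test_identical_seed_identical_stream(self):
        a = RandomEngine(42).generator.uniform(size=100)
        b = RandomEngine(42).generator.uniform(size=100)
        assert np.array_equal(a, b)

    def test_spawned_engines_differ(self):
        kids = RandomEngine(1).spawn(3)
        draws = [k.generator.uniform(size=10) for k in kids]
        assert not np.array_equal(draws[0], draws[1])
        again = RandomEngine(1).spawn(3)
        assert np.array_equal(draws[2], again[2].generator.uniform(size=10))


class TestNaturalCoordinates:
    CELL = (np.zeros(3), np.array([2.0, 4.0, 1.0]))

    def test_center(self):
        assert np.allclose(natural_coordinates(self.CELL, [1.0, 2.0, 0.5]), 0.0)

    def test_corner(self):
        assert np.allclose(natural_coordinates(self.CELL, [2.0, 4.0, 1.0]), 1.0)
        assert np.allclose(natural_coordinates(self.CELL, [0.0, 0.0, 0.0]), -1.0)

    def test_quarter_along_x(self):
        xi = natural_coordinates(self.CELL, [0.5, 2.0, 0.5])
        assert xi[0] == pytest.approx(-0.5, abs=1e-12)

    def test_outside_rejected(self):
        with pytest.raises(OutOfDomainError):
            natural_coordinates(self.CELL, [2.5, 1.0, 0.5])

    def test_trilinear_round_trip(self, rng):
        lo, hi = self.CELL
        for _ in range(20):
            x = rng.uniform(lo, hi)
            xi = natural_coordinates(self.CELL, x)
            assert np.allclose(lo + 0.5 * (xi + 1) * (hi - lo), x, atol=1e-12)


class TestInterpolationWeights:
    def test_center_all_equal(self):
        w = interpolation_weights(np.zeros(3))
        assert np.allclose(w, 0.125)

    def test_corner_delta(self):
        w = interpolation_weights(np.array([1.0, 1.0, 1.0]))
        assert w.max() == pytest.approx(1.0)
        assert w.sum() == pytest.approx(1.0)
        assert np.count_nonzero(w) == 1

    def test_direct_evaluation_half_x(self):
        # (1/8)(1 +- 0.5) * 1 * 1 -> four weights of 1/16 and four of 3/16
        w = np.sort(interpolation_weights(np.array([0.5, 0.0, 0.0])))
        assert np.allclose(w[:4], 0.0625)
        assert np.allclose(w[4:], 0.1875)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_outside_cube_rejected(self):
        with pytest.raises(InvalidParameterError):
            interpolation_weights(np.array([1.2, 0.0, 0.0]))


class TestGeodesicInterpolate:
    W8 = np.full(8, 0.125)

    def test_identical_inputs(self):
        P = np.diag([3.0, 2, 1])
        out = geodesic_interpolate([EFD(P)] * 8, self.W8)
        assert np.allclose(out.tensor, P, atol=1e-12)

    def test_weight_one_selects_input(self):
        efds = [EFD(np.diag([1.0 + i, 1, 1])) for i in range(8)]
        w = np.zeros(8)
        w[3] = 1.0
        assert np.allclose(geodesic_interpolate(efds, w).tensor, efds[3].tensor)

    def test_commuting_geometric_mean(self):
        a, b = EFD(np.eye(3)), EFD(np.e**2 * np.eye(3))
        out = geodesic_interpolate([a, b], [0.5, 0.5])
        assert np.allclose(out.tensor, np.e * np.eye(3), atol=1e-12)

    def test_eigenvalue_bounds_commuting(self, rng):
        vals = rng.uniform(0.5, 4.0, (8, 3))
        efds = [EFD(np.diag(v)) for v in vals]
        w = rng.uniform(0, 1, 8)
        w /= w.sum()
        out = geodesic_interpolate(efds, w)
        assert out.radii.max() <= vals.max() + 1e-9
        assert out.radii.min() >= vals.min() - 1e-9

    def test_always_spd_random_inputs(self, rng):
        for _ in range(20):
            efds = []
            for _ in range(8):
                R = random_rotation(rng)
                efds.append(EFD(R @ np.diag(rng.uniform(0.2, 5, 3)) @ R.T))
            w = rng.uniform(0, 1, 8)
            w /= w.sum()
            out = geodesic_interpolate(efds, w)
            assert np.linalg.eigvalsh(out.tensor)[0] > 0

    def test_affine_mean_agrees_for_commuting(self):
        a, b = EFD(np.diag([1.0, 2, 3])), EFD(np.diag([4.0, 5, 6]))
        le = geodesic_interpolate([a, b], [0.5, 0.5], mean="log_euclidean")
        ai = geodesic_interpolate([a, b], [0.5, 0.5], mean="affine")
        assert np.allclose(le.tensor, ai.tensor, atol=1e-8)


class TestVectorInterpolate:
    def test_identical_vectors(self):
        v = np.array([0.0, 0, 1])
        assert np.allclose(vector_interpolate([v] * 4, np.full(4, 0.25)), v)

    def test_weight_one(self):
        vs = np.eye(3)
        w = np.array([0.0, 1.0, 0.0])
        assert np.allclose(vector_interpolate(vs, w), [0, 1, 0])

    def test_equal_xy_mix(self):
        out = vector_interpolate(np.eye(3)[:2], [0.5, 0.5])
        assert np.allclose(out, [np.sqrt(0.5), np.sqrt(0.5), 0.0])

    def test_cancelling_fallback(self):
        vs = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        out = vector_interpolate(vs, [0.5, 0.5])
        assert np.allclose(np.abs(out), [1, 0, 0])
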