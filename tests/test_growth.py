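"""Growth rules: direction update, velocity scale, rates, stepping, branching."""

import numpy as np
import pytest
from scipy import integrate, stats

from efdangio import (
    GrowthConfig,
    InvalidParameterError,
    RandomEngine,
    build_uniform_culture,
    grow_step,
    growth_direction,
    linear_rate_with_arrest,
    seed_fragments,
    sigmoid_rate,
    simulate,
    velocity_scale,
)
from efdangio.growth import REFERENCE_FA, VesselNetwork, _SimState, branch_step


class TestGrowthDirection:
    X = np.array([1.0, 0, 0])
    Y = np.array([0.0, 1, 0])

    def test_alpha_zero_returns_psi(self):
        assert np.array_equal(growth_direction(self.X, self.Y, 0.0), self.X)

    def test_alpha_one_returns_theta(self):
        assert np.array_equal(growth_direction(self.X, self.Y, 1.0), self.Y)

    def test_midpoint_is_45_degrees(self):
        out = growth_direction(self.X, self.Y, 0.5)
        assert np.allclose(out, [np.sqrt(0.5), np.sqrt(0.5), 0.0], atol=1e-12)

    def test_parallel_inputs_unchanged(self):
        assert np.allclose(growth_direction(self.X, self.X, 0.7), self.X)

    def test_no_overshoot_angle_identity(self, rng):
        # angle(psi_new, theta) = (1 - alpha) * angle(psi, theta) exactly
        for _ in range(100):
            psi = rng.normal(size=3)
            psi /= np.linalg.norm(psi)
            theta = rng.normal(size=3)
            theta /= np.linalg.norm(theta)
            if psi @ theta < 0:
                theta = -theta
            alpha = rng.uniform(0, 1)
            out = growth_direction(psi, theta, alpha)
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)
            a0 = np.arccos(np.clip(psi @ theta, -1, 1))
            a1 = np.arccos(np.clip(out @ theta, -1, 1))
            assert a1 == pytest.approx((1 - alpha) * a0, abs=1e-9)
            # coplanarity
            assert abs(np.cross(psi, theta) @ out) < 1e-9


class TestVelocityScale:
    CFG = GrowthConfig()

    def test_calibration_constraint(self):
        assert velocity_scale(3.0, REFERENCE_FA, self.CFG) == pytest.approx(1.0)

    def test_floor(self, rng):
        rho = rng.uniform(0.5, 10, 100)
        fa = rng.uniform(0, 1, 100)
        assert np.all(velocity_scale(rho, fa, self.CFG) >= self.CFG.nu_d)

    def test_monotone_in_density_and_anisotropy(self):
        assert velocity_scale(4.0, 0.3, self.CFG) < velocity_scale(3.0, 0.3, self.CFG)
        assert velocity_scale(5.0, 0.3, self.CFG) < velocity_scale(4.0, 0.3, self.CFG)
        assert velocity_scale(3.0, 0.9, self.CFG) > velocity_scale(3.0, 0.1, self.CFG)

    def test_non_positive_density_rejected(self):
        with pytest.raises(InvalidParameterError):
            velocity_scale(0.0, 0.5, self.CFG)


class TestRates:
    CFG = GrowthConfig()

    def test_sigmoid_tails_vanish(self):
        assert sigmoid_rate(0.0, self.CFG) < sigmoid_rate(5.0, self.CFG) / 10
        assert sigmoid_rate(30.0, self.CFG) < 1e-6

    def test_sigmoid_peak_at_midpoint(self):
        t = np.linspace(0, 10, 401)
        assert t[np.argmax(sigmoid_rate(t, self.CFG))] == pytest.approx(
            self.CFG.sigmoid_midpoint, abs=0.05
        )

    def test_sigmoid_integral_quadrature_oracle(self):
        total, _ = integrate.quad(lambda t: sigmoid_rate(t, self.CFG), 0.0, 10.0)
        sig = lambda t: 1.0 / (
            1.0 + np.exp(-self.CFG.sigmoid_slope * (t - self.CFG.sigmoid_midpoint))
        )
        expected = self.CFG.sigmoid_amplitude * (sig(10.0) - sig(0.0))
        assert total == pytest.approx(expected, rel=1e-8)

    def test_arrest_above_threshold(self):
        assert linear_rate_with_arrest(5.0, self.CFG.w_thresh * 1.01, self.CFG) == 0.0

    def test_plateau_after_ramp(self):
        assert linear_rate_with_arrest(5.0, 0.0, self.CFG) == pytest.approx(
            self.CFG.linear_rate
        )

    def test_threshold_one_never_hit(self):
        cfg = GrowthConfig(w_thresh=1.0)
        t = np.array([0.5, 1.0, 3.0, 9.0])
        ramped = cfg.linear_rate * np.clip(t / cfg.linear_ramp_days, 0, 1)
        assert np.allclose(linear_rate_with_arrest(t, 0.5, cfg), ramped)


def _tiny_setup(seed=3, **cfg_kw):
    grid = build_uniform_culture("high", extent=0.5)
    rng = RandomEngine(seed)
    network = seed_fragments(grid, rng, n=10)
    config = GrowthConfig(branching_enabled=False, **cfg_kw)
    return grid, network, config, rng


class TestGrowStep:
    def test_zero_velocity_leaves_network_unchanged(self):
        grid, network, config, rng = _tiny_setup(nu_a=0.0, nu_d=0.0)
        n0 = network.n_segments
        length0 = network.total_length()
        grow_step(network, grid, config, rng, t=5.0)
        assert network.n_segments == n0
        assert network.total_length() == pytest.approx(length0)

    def test_alpha_one_uniaxial_field_aligns_first_step(self):
        grid = build_uniform_culture("high", extent=0.5)
        # make the field effectively one-dimensional along x
        from efdangio import EFD

        grid.set_uniform_efd(EFD(np.diag([20.0, 1.0, 1.0])))
        rng = RandomEngine(0)
        network = VesselNetwork()
        seg = network.add_segments([[0.25, 0.25, 0.25]], [[0.26, 0.25, 0.25]], [-1], 0.0)
        network.add_tips([[0.26, 0.25, 0.25]], [[1.0, 0.0, 0.0]], seg)
        config = GrowthConfig(alpha=1.0, branching_enabled=False)
        grow_step(network, grid, config, rng, t=5.0)
        d = network.end[-1] - network.start[-1]
        d /= np.linalg.norm(d)
        assert abs(d[0]) > 0.99

    def test_added_length_bookkeeping(self):
        grid, network, config, rng = _tiny_setup()
        state = _SimState(grid)
        before = network.total_length()
        n_tips = network.n_active_tips
        t = 5.0
        grow_step(network, grid, config, rng, t, state)
        added = network.total_length() - before
        # every tip that stayed inside adds rate*nu*dt; the sum is bounded above
        # by n_tips * max step and below by zero
        assert 0 < added <= n_tips * 0.5 * grid.min_cell_edge + 1e-12

    def test_boundary_deactivation(self):
        grid = build_uniform_culture("low", extent=0.5)
        rng = RandomEngine(0)
        network = VesselNetwork()
        seg = network.add_segments([[0.49, 0.25, 0.25]], [[0.498, 0.25, 0.25]], [-1], 0.0)
        network.add_tips([[0.498, 0.25, 0.25]], [[1.0, 0.0, 0.0]], seg)
        config = GrowthConfig(alpha=0.0, branching_enabled=False)
        for _ in range(5):
            grow_step(network, grid, config, rng, t=5.0)
        assert network.n_active_tips == 0
        assert grid.contains(network.end).all()


class TestBranchStep:
    def test_disabled_branching_spawns_nothing(self):
        grid, network, config, rng = _tiny_setup()
        config = config.with_(branching_enabled=False)
        n0 = len(network.tip_pos)
        grow_step(network, grid, config, rng, 5.0)
        branch_step(network, config, rng, 5.0)
        assert len(network.tip_pos) == n0

    def test_zenith_point_mass_at_90(self, rng):
        from efdangio.growth import _branch_directions

        psi = rng.normal(size=(5000, 3))
        psi /= np.linalg.norm(psi, axis=1, keepdims=True)
        zen = np.full(5000, np.pi / 2)
        azi = rng.uniform(0, 2 * np.pi, 5000)
        d = _branch_directions(psi, zen, azi)
        angles = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", d, psi), -1, 1)))
        assert np.abs(angles - 90.0).max() < 1e-6

    def test_azimuth_uniform_circle(self):
        # Rayleigh test of circular uniformity around the parent axis
        from efdangio.growth import _branch_directions

        gen = np.random.default_rng(5)
        n = 10**4
        psi = np.tile([0.0, 0.0, 1.0], (n, 1))
        zen = np.full(n, np.deg2rad(60.0))
        azi = gen.uniform(0, 2 * np.pi, n)
        d = _branch_directions(psi, zen, azi)
        phi = np.arctan2(d[:, 1], d[:, 0])
        R = np.hypot(np.cos(phi).mean(), np.sin(phi).mean())
        p = np.exp(-n * R**2)  # Rayleigh approximation
        assert p > 0.01

    def test_branches_appear_with_growth(self):
        grid = build_uniform_culture("low", extent=0.5)
        rng = RandomEngine(2)
        network = seed_fragments(grid, rng, n=20)
        config = GrowthConfig(branching_enabled=True, branch_threshold_mean=0.02)
        n0 = len(network.tip_pos)
        simulate(network, grid, config, rng, duration=10.0)
        assert len(network.tip_pos) > n0
        # branches anchor on existing segment starts
        assert grid.contains(network.start).all()


class TestDeterminism:
    def test_identical_seed_bit_identical_table(self):
        tables = []
        for _ in range(2):
            grid = build_uniform_culture("med", extent=0.5)
            rng = RandomEngine(11)
            network = seed_fragments(grid, rng, n=15)
            simulate(network, grid, GrowthConfig(), rng, duration=6.0)
            tables.append(network.to_frame())
        assert tables[0].equals(tables[1])

    def test_different_seeds_differ(self):
        nets = []
        for seed in (1, 2):
            grid = build_uniform_culture("med", extent=0.5)
            rng = RandomEngine(seed)
            network = seed_fragments(grid, rng, n=15)
            simulate(network, grid, GrowthConfig(), rng, duration=4.0)
            nets.append(network.total_length())
        assert nets[0] != nets[1]
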