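"""Discrete microvessel network growth.

Vessel networks are forests of straight line segments.  Each active tip
advances once per time step: a contact-guidance direction ``theta`` is drawn
from the locally interpolated (EFD or legacy vector) field, the tip
orientation ``psi`` is partially rotated toward ``theta`` by the fibril
weight ``alpha``, and the tip extends by ``rate(t) * nu(rho, FA) * dt``.
Branches appear stochastically on recently grown segments.

All stochastic draws flow through a single seeded engine in a fixed order, so
an identical seed and configuration replays an identical segment table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .efd import fractional_anisotropy
from .errors import InvalidParameterError
from .grid import DomainGrid
from .sampling import RandomEngine, _as_generator

__all__ = [
    "GrowthConfig",
    "VesselNetwork",
    "growth_direction",
    "velocity_scale",
    "sigmoid_rate",
    "linear_rate_with_arrest",
    "grow_step",
    "branch_step",
    "simulate",
]

#: FA of the low-anisotropy reference matrix (radii 1.3, 1.0, 0.5) used to
#: normalize the velocity scale against unaligned 3 mg/mL collagen.
REFERENCE_FA = fractional_anisotropy(np.array([1.3, 1.0, 0.5]))


@dataclass
class GrowthConfig:
    """All tunable growth parameters.

    The Lorentzian velocity scale is
    ``nu(rho, FA) = a / ((1 + ((rho - rho0)/b)^2) (1 + ((FA - FA0)/c)^2)) + d``
    with the center ``(rho0, FA0)`` placed below the physiologic density range
    and at full alignment, so growth slows with density over 3-5 mg/mL and
    accelerates with anisotropy over [0, 1].  ``a`` is rescaled at load time
    so that ``nu(rho_ref, fa_ref) = nu_a`` exactly (growth normalized to the
    unaligned 3 mg/mL reference); ``d`` is a floor sustaining minimal growth.
    """

    alpha: float = 0.3  # fibril weight: 0 = pure persistence, 1 = pure guidance
    mode: str = "efd"  # "efd" or "vector" (legacy comparison)
    # Lorentzian velocity-scale coefficients
    nu_a: float = 1.0
    nu_b: float = 0.7  # mg/mL half-width
    nu_c: float = 0.8  # FA half-width
    nu_d: float = 0.05  # non-negative growth floor
    nu_rho0: float = 2.5  # mg/mL center
    nu_fa0: float = 1.0  # FA center
    nu_rho_ref: float = 3.0  # calibration density, mg/mL
    nu_fa_ref: float = REFERENCE_FA  # calibration anisotropy
    # sigmoidal total-length curve L(t) = amplitude * logistic(slope*(t - midpoint))
    sigmoid_amplitude: float = 0.8  # mm per tip over the culture
    sigmoid_midpoint: float = 5.0  # day
    sigmoid_slope: float = 1.0  # 1/day
    # linear rule with volume-fraction arrest
    linear_rate: float = 0.2  # mm/day plateau
    linear_ramp_days: float = 2.0  # initial lag before full rate
    rate_rule: str = "sigmoid"  # "sigmoid" or "linear"
    w_thresh: float = 0.01  # local vessel volume fraction that arrests extension
    vessel_radius_um: float = 5.0
    dt: float = 0.25  # days
    # branching
    branching_enabled: bool = True
    branch_threshold_mean: float = 0.15  # mm of lineage growth per branch (exponential)
    branch_zenith_mean_deg: float = 60.0
    branch_zenith_sd_deg: float = 15.0
    # interpolation
    geodesic_mean: str = "log_euclidean"
    init_alpha: float = 0.3  # fibril weight applied once at fragment seeding

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParameterError("alpha must lie in [0, 1]")
        if self.mode not in ("efd", "vector"):
            raise InvalidParameterError("mode must be 'efd' or 'vector'")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.nu_d < 0:
            raise InvalidParameterError("nu_d must be non-negative")
        if not 0.0 < self.w_thresh <= 1.0:
            raise InvalidParameterError("w_thresh must lie in (0, 1]")
        # rescale the Lorentzian amplitude so nu(rho_ref, fa_ref) == nu_a
        denom_ref = (1.0 + ((self.nu_rho_ref - self.nu_rho0) / self.nu_b) ** 2) * (
            1.0 + ((self.nu_fa_ref - self.nu_fa0) / self.nu_c) ** 2
        )
        self._nu_a_eff = (self.nu_a - self.nu_d) * denom_ref

    def with_(self, **kw) -> "GrowthConfig":
        return replace(self, **kw)


def velocity_scale(rho, fa, config: GrowthConfig):
    """Lorentzian growth-velocity scale ``nu(rho, FA)``.

    Decreases away from the density center, increases toward the anisotropy
    center, never drops below the floor ``nu_d``.  Accepts scalars or arrays.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise InvalidParameterError("density must be positive")
    fa = np.asarray(fa, dtype=float)
    val = config._nu_a_eff / (
        (1.0 + ((rho - config.nu_rho0) / config.nu_b) ** 2)
        * (1.0 + ((fa - config.nu_fa0) / config.nu_c) ** 2)
    ) + config.nu_d
    return float(val) if val.ndim == 0 else val


def sigmoid_rate(t, config: GrowthConfig):
    """Tip extension rate (mm/day): time derivative of the sigmoidal length curve."""
    t = np.asarray(t, dtype=float)
    z = config.sigmoid_slope * (t - config.sigmoid_midpoint)
    sig = 1.0 / (1.0 + np.exp(-z))
    val = config.sigmoid_amplitude * config.sigmoid_slope * sig * (1.0 - sig)
    return float(val) if val.ndim == 0 else val


def linear_rate_with_arrest(t, local_volume_fraction, config: GrowthConfig):
    """Ramped linear rate (mm/day), zero once the local volume fraction exceeds ``w_thresh``."""
    t = np.asarray(t, dtype=float)
    w = np.asarray(local_volume_fraction, dtype=float)
    ramp = np.clip(t / config.linear_ramp_days, 0.0, 1.0) if config.linear_ramp_days > 0 else np.ones_like(t)
    val = np.where(w > config.w_thresh, 0.0, config.linear_rate * ramp)
    return float(val) if val.ndim == 0 else val


def growth_direction(psi, theta, alpha: float) -> np.ndarray:
    """Rotate ``psi`` toward ``theta`` by the fraction ``alpha`` of their angle.

    The rotation is about ``u = psi x theta`` so the result is coplanar with
    the inputs; ``alpha = 0`` returns ``psi`` and ``alpha = 1`` returns
    ``theta`` exactly.  Parallel inputs return ``psi`` unchanged.
    """
    psi = np.asarray(psi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not 0.0 <= alpha <= 1.0:
        raise InvalidParameterError("alpha must lie in [0, 1]")
    if alpha == 0.0:
        return psi.copy()
    if alpha == 1.0:
        return theta.copy()
    return growth_directions(psi[None, :], theta[None, :], alpha)[0]


def growth_directions(psi: np.ndarray, theta: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized :func:`growth_direction` for (n, 3) inputs."""
    if alpha == 0.0:
        return psi.copy()
    if alpha == 1.0:
        return theta.copy()
    dot = np.clip(np.einsum("ij,ij->i", psi, theta), -1.0, 1.0)
    axis = np.cross(psi, theta)
    nrm = np.linalg.norm(axis, axis=1)
    out = psi.copy()
    ok = nrm >= 1e-12
    if np.any(ok):
        u = axis[ok] / nrm[ok][:, None]
        ang = alpha * np.arccos(dot[ok])
        c, s = np.cos(ang)[:, None], np.sin(ang)[:, None]
        p = psi[ok]
        # Rodrigues: p cos + (u x p) sin + u (u.p)(1 - cos); u.p = 0 would be exact
        out[ok] = p * c + np.cross(u, p) * s + u * (np.einsum("ij,ij->i", u, p)[:, None]) * (1.0 - c)
        out[ok] /= np.linalg.norm(out[ok], axis=1, keepdims=True)
    return out


class VesselNetwork:
    """A forest of vessel segments with active growing tips."""

    def __init__(self):
        self.start = np.empty((0, 3))
        self.end = np.empty((0, 3))
        self.parent = np.empty(0, dtype=np.int64)
        self.birth = np.empty(0)
        # tip state
        self.tip_pos = np.empty((0, 3))
        self.tip_psi = np.empty((0, 3))
        self.tip_seg = np.empty(0, dtype=np.int64)  # segment whose end is this tip
        self.tip_growth = np.empty(0)  # lineage growth since last branch event
        self.tip_thresh = np.empty(0)  # next branch threshold (mm)
        self.tip_active = np.empty(0, dtype=bool)
        # recent segments (created during the last growth step), for branching
        self.recent = np.empty(0, dtype=np.int64)

    @property
    def n_segments(self) -> int:
        return len(self.start)

    @property
    def n_active_tips(self) -> int:
        return int(self.tip_active.sum())

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.end - self.start, axis=1)

    def total_length(self) -> float:
        return float(self.segment_lengths().sum())

    def add_segments(self, start, end, parent, birth) -> np.ndarray:
        """Append segments; returns their indices."""
        start = np.atleast_2d(start)
        n0 = self.n_segments
        self.start = np.vstack([self.start, start])
        self.end = np.vstack([self.end, np.atleast_2d(end)])
        self.parent = np.concatenate([self.parent, np.atleast_1d(parent).astype(np.int64)])
        self.birth = np.concatenate([self.birth, np.broadcast_to(birth, (len(start),))])
        return np.arange(n0, self.n_segments)

    def add_tips(self, pos, psi, seg, growth=0.0, thresh=np.inf, active=True) -> np.ndarray:
        pos = np.atleast_2d(pos)
        n = len(pos)
        n0 = len(self.tip_pos)
        self.tip_pos = np.vstack([self.tip_pos, pos])
        self.tip_psi = np.vstack([self.tip_psi, np.atleast_2d(psi)])
        self.tip_seg = np.concatenate([self.tip_seg, np.atleast_1d(seg).astype(np.int64)])
        self.tip_growth = np.concatenate([self.tip_growth, np.broadcast_to(growth, (n,))])
        self.tip_thresh = np.concatenate([self.tip_thresh, np.broadcast_to(thresh, (n,))])
        self.tip_active = np.concatenate([self.tip_active, np.broadcast_to(active, (n,))])
        return np.arange(n0, len(self.tip_pos))

    def orientations(self) -> np.ndarray:
        """Unit segment orientations (positive-length segments only)."""
        d = self.end - self.start
        L = np.linalg.norm(d, axis=1)
        ok = L > 0
        return d[ok] / L[ok][:, None]

    def to_frame(self) -> pd.DataFrame:
        """Segment table: one row per segment."""
        tip_flag = np.zeros(self.n_segments, dtype=bool)
        live = self.tip_seg[self.tip_active]
        tip_flag[live[live >= 0]] = True
        return pd.DataFrame(
            {
                "segment": np.arange(self.n_segments),
                "parent": self.parent,
                "t_birth": self.birth,
                "x0": self.start[:, 0],
                "y0": self.start[:, 1],
                "z0": self.start[:, 2],
                "x1": self.end[:, 0],
                "y1": self.end[:, 1],
                "z1": self.end[:, 2],
                "tip": tip_flag,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_vtk(self, path) -> None:
        """Export the network as legacy VTK polylines (one line per segment)."""
        from ._vtk import write_polydata

        pts = np.vstack([self.start, self.end])
        n = self.n_segments
        lines = [np.array([i, i + n]) for i in range(n)]
        write_polydata(path, pts, lines=lines)


class _SimState:
    """Per-simulation bookkeeping not owned by the network (cell length tallies)."""

    def __init__(self, grid: DomainGrid):
        self.cell_length = np.zeros(grid.n_cells)

    def volume_fraction(self, grid: DomainGrid, radius_mm: float) -> np.ndarray:
        return self.cell_length * np.pi * radius_mm**2 / grid.cell_volumes


def _sample_theta_batch(radii, axes, gen) -> np.ndarray:
    """Vectorized rejection sampling of one direction per tip from per-tip EFDs."""
    n = len(radii)
    out = np.empty((n, 3))
    pending = np.arange(n)
    inv_sq = 1.0 / radii**2
    bmax = radii[:, 0]
    it = 0
    while len(pending):
        it += 1
        if it > 10**6:
            raise InvalidParameterError("rejection sampling iteration cap exceeded")
        r = gen.uniform(-1.0, 1.0, size=(len(pending), 3)) * bmax[pending][:, None]
        ok = (r**2 * inv_sq[pending]).sum(axis=1) < 1.0
        hit = pending[ok]
        out[hit] = r[ok]
        pending = pending[~ok]
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    # rotate principal-frame samples into the global frame
    return np.einsum("nij,nj->ni", axes, out)


def grow_step(
    network: VesselNetwork,
    grid: DomainGrid,
    config: GrowthConfig,
    rng,
    t: float,
    state: _SimState = None,
) -> VesselNetwork:
    """Advance every active tip by one time step (in place).

    Per tip: interpolate the local field, sample a guidance direction, rotate
    the tip orientation, extend by ``rate * nu * dt`` (capped at half the
    smallest cell edge).  Tips leaving the domain are clipped to the boundary
    and deactivated; extension stops in cells whose vessel volume fraction
    exceeds ``w_thresh``.
    """
    gen = _as_generator(rng)
    if state is None:
        state = _SimState(grid)
    act = np.flatnonzero(network.tip_active)
    if len(act) == 0:
        return network
    pos = network.tip_pos[act]
    psi = network.tip_psi[act]
    inside = grid.contains(pos)
    if np.any(~inside):  # defensive: deactivate stragglers, never raise
        network.tip_active[act[~inside]] = False
        act = act[inside]
        pos, psi = pos[inside], psi[inside]
        if len(act) == 0:
            return network
    cells = grid.locate(pos)

    if config.mode == "efd":
        radii, axes, rho = grid.interpolate_fields(pos, cells)
        b = radii
        fa = np.sqrt(
            0.5 * ((b[:, 0] - b[:, 1]) ** 2 + (b[:, 1] - b[:, 2]) ** 2 + (b[:, 2] - b[:, 0]) ** 2)
        ) / np.linalg.norm(b, axis=1)
        theta = _sample_theta_batch(radii, axes, gen)
    else:
        theta = grid.interpolate_vectors(pos, psi, cells)
        # FA and density still come from the stored EFD/density fields
        radii, _, rho = grid.interpolate_fields(pos, cells)
        b = radii
        fa = np.sqrt(
            0.5 * ((b[:, 0] - b[:, 1]) ** 2 + (b[:, 1] - b[:, 2]) ** 2 + (b[:, 2] - b[:, 0]) ** 2)
        ) / np.linalg.norm(b, axis=1)

    # axial convention: flip theta into psi's hemisphere (ties keep the raw sample)
    sign = np.sign(np.einsum("ij,ij->i", theta, psi))
    sign[sign == 0] = 1.0
    theta = theta * sign[:, None]

    if config.rate_rule == "sigmoid":
        base = np.full(len(act), sigmoid_rate(t, config))
        if config.w_thresh < 1.0:
            w_local = state.volume_fraction(grid, config.vessel_radius_um * 1e-3)[cells]
            base = np.where(w_local > config.w_thresh, 0.0, base)
    elif config.rate_rule == "linear":
        w_local = state.volume_fraction(grid, config.vessel_radius_um * 1e-3)[cells]
        base = linear_rate_with_arrest(np.full(len(act), float(t)), w_local, config)
    else:
        raise InvalidParameterError(f"unknown rate rule {config.rate_rule!r}")

    nu = velocity_scale(rho, fa, config)
    step_len = np.minimum(base * nu * config.dt, 0.5 * grid.min_cell_edge)

    psi_new = growth_directions(psi, theta, config.alpha)
    grew = step_len > 0.0
    if not np.any(grew):
        network.recent = np.empty(0, dtype=np.int64)
        return network

    gidx = act[grew]
    p0 = pos[grew]
    d = psi_new[grew]
    L = step_len[grew]
    p1 = p0 + d * L[:, None]

    # clip tips exiting the domain to the boundary and deactivate them
    lo = grid.origin
    hi = grid.origin + grid.extent
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo[None, :] - p0) / np.where(d != 0, d, np.nan)
        t_hi = (hi[None, :] - p0) / np.where(d != 0, d, np.nan)
    t_exit = np.nanmin(np.where(np.maximum(t_lo, t_hi) > 0, np.maximum(t_lo, t_hi), np.inf), axis=1)
    outside = ~grid.contains(p1)
    t_cut = np.where(outside, np.minimum(t_exit, L), L)
    t_cut = np.clip(t_cut, 0.0, L)
    p1 = p0 + d * t_cut[:, None]
    L_actual = t_cut

    seg_idx = network.add_segments(p0, p1, network.tip_seg[gidx], t)
    mid = 0.5 * (p0 + p1)
    mid_in = grid.contains(mid)
    if np.any(mid_in):
        np.add.at(state.cell_length, grid.locate(mid[mid_in]), L_actual[mid_in])

    network.tip_pos[gidx] = p1
    network.tip_psi[gidx] = d
    network.tip_seg[gidx] = seg_idx
    network.tip_growth[gidx] += L_actual
    network.tip_active[gidx] = network.tip_active[gidx] & ~outside
    network.recent = seg_idx
    return network


def _branch_directions(psi: np.ndarray, zenith: np.ndarray, azimuth: np.ndarray) -> np.ndarray:
    """Direction at ``zenith`` from each parent axis, azimuth uniform about it."""
    ref = np.where(
        np.abs(psi[:, [0]]) < 0.9, np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]])
    )
    e1 = np.cross(psi, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(psi, e1)
    circ = np.cos(azimuth)[:, None] * e1 + np.sin(azimuth)[:, None] * e2
    return np.cos(zenith)[:, None] * psi + np.sin(zenith)[:, None] * circ


def branch_step(network: VesselNetwork, config: GrowthConfig, rng, t: float) -> VesselNetwork:
    """Spawn branch tips on recently grown segments (in place).

    A tip whose accumulated lineage growth exceeds its exponential threshold
    sprouts one branch at the start of its newest segment.  The branch
    direction is the parent direction rotated by a zenith angle (truncated
    normal) about an axis set by an azimuth angle uniform on [0, 2 pi).
    """
    gen = _as_generator(rng)
    if not config.branching_enabled or config.branch_threshold_mean <= 0:
        return network
    ready = np.flatnonzero(
        network.tip_active & (network.tip_growth >= network.tip_thresh)
    )
    # restrict to lineages whose newest segment was grown this step
    if len(network.recent):
        ready = ready[np.isin(network.tip_seg[ready], network.recent)]
    else:
        ready = ready[:0]
    if len(ready) == 0:
        return network
    n = len(ready)
    psi = network.tip_psi[ready]
    zen = np.deg2rad(
        np.clip(
            gen.normal(config.branch_zenith_mean_deg, config.branch_zenith_sd_deg, n),
            0.0,
            180.0,
        )
    )
    azi = gen.uniform(0.0, 2.0 * np.pi, n)
    d = _branch_directions(psi, zen, azi)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    origin = network.start[network.tip_seg[ready]]
    network.add_tips(
        origin,
        d,
        network.tip_seg[ready],
        growth=0.0,
        thresh=gen.exponential(config.branch_threshold_mean, n),
        active=True,
    )
    network.tip_growth[ready] -= network.tip_thresh[ready]
    network.tip_thresh[ready] = gen.exponential(config.branch_threshold_mean, n)
    return network


def simulate(
    network: VesselNetwork,
    grid: DomainGrid,
    config: GrowthConfig,
    rng,
    duration: float,
) -> VesselNetwork:
    """Run growth (and branching, if enabled) from t=0 to ``duration`` days."""
    if isinstance(rng, int):
        rng = RandomEngine(rng)
    state = _SimState(grid)
    if config.branching_enabled:
        gen = _as_generator(rng)
        uninit = ~np.isfinite(network.tip_thresh)
        if np.any(uninit):
            network.tip_thresh[uninit] = gen.exponential(
                config.branch_threshold_mean, int(uninit.sum())
            )
    # account for seeded fragment length in the arrest tally
    if network.n_segments:
        mids = 0.5 * (network.start + network.end)
        ok = grid.contains(mids)
        if np.any(ok):
            np.add.at(
                state.cell_length, grid.locate(mids[ok]), network.segment_lengths()[ok]
            )
    n_steps = int(round(duration / config.dt))
    for k in range(n_steps):
        t = k * config.dt
        grow_step(network, grid, config, rng, t, state)
        if config.branching_enabled:
            branch_step(network, config, rng, t)
    return network
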