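"""Network morphometry: ODFs, ellipse fits, regional vascularization, replicates.

Segment orientations are axial quantities (a vessel running +x is the same
observation as one running -x), so planar ODFs live on 180 one-degree bins
over [0, 180) and 3-D ODFs are antipodally symmetrized.  All histograms are
weighted by segment length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .grid import DomainGrid
from .growth import GrowthConfig, VesselNetwork, simulate
from .sampling import RandomEngine
from .scenarios import ScenarioSpec, seed_fragments
from .sphere import ODFHistogram, SphereMesh, histogram_from_directions

__all__ = [
    "NetworkMetrics",
    "network_odf",
    "planar_odf",
    "fit_axis_ratio",
    "regional_lengths",
    "run_replicates",
    "AXIS_RATIO_CAP",
]

PLANAR_BINS = 180
AXIS_RATIO_CAP = 50.0

_PROJ_AXES = {"xy": (0, 1), "xz": (0, 2)}


@dataclass
class NetworkMetrics:
    """Morphometric summary of one vessel network."""

    total_length: float  # mm
    region_length: dict  # mm per named region
    vascularity: dict  # mm / mm^3 per named region
    xy_axis_ratio: float
    xz_axis_ratio: float

    def as_dict(self) -> dict:
        out = {"total_length": self.total_length}
        for k, v in self.region_length.items():
            out[f"length_{k}"] = v
        for k, v in self.vascularity.items():
            out[f"vascularity_{k}"] = v
        out["xy_axis_ratio"] = self.xy_axis_ratio
        out["xz_axis_ratio"] = self.xz_axis_ratio
        return out


def _segments_of(network) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(network, VesselNetwork):
        start, end = network.start, network.end
    elif isinstance(network, pd.DataFrame):
        start = network[["x0", "y0", "z0"]].to_numpy(float)
        end = network[["x1", "y1", "z1"]].to_numpy(float)
    else:
        raise InvalidParameterError("network must be a VesselNetwork or segment table")
    L = np.linalg.norm(end - start, axis=1)
    keep = L > 0
    return start[keep], end[keep]


def planar_odf(network, projection: str = "xy") -> np.ndarray:
    """Length-weighted axial histogram over 180 one-degree bins in a plane."""
    if projection not in _PROJ_AXES:
        raise InvalidParameterError("projection must be 'xy' or 'xz'")
    start, end = _segments_of(network)
    if len(start) == 0:
        raise InvalidParameterError("network has no segments of positive length")
    a, b = _PROJ_AXES[projection]
    d = end - start
    L = np.linalg.norm(d, axis=1)
    ang = np.degrees(np.arctan2(d[:, b], d[:, a])) % 180.0
    bins = np.minimum((ang // (180.0 / PLANAR_BINS)).astype(int), PLANAR_BINS - 1)
    mass = np.zeros(PLANAR_BINS)
    np.add.at(mass, bins, L)
    return mass / mass.sum()


def network_odf(network, projection: str = "none", mesh: SphereMesh = None):
    """Length-weighted ODF of segment orientations.

    ``projection='none'`` returns a symmetrized :class:`ODFHistogram` on the
    given icosphere; ``'xy'``/``'xz'`` return a planar 180-bin axial mass
    array (1-degree bins).
    """
    if projection in _PROJ_AXES:
        return planar_odf(network, projection)
    if projection != "none":
        raise InvalidParameterError("projection must be 'xy', 'xz' or 'none'")
    if mesh is None:
        raise InvalidParameterError("a sphere mesh is required for 3-D ODFs")
    start, end = _segments_of(network)
    if len(start) == 0:
        raise InvalidParameterError("network has no segments of positive length")
    d = end - start
    L = np.linalg.norm(d, axis=1)
    return histogram_from_directions(d / L[:, None], mesh, symmetrize=True, weights=L)


def fit_axis_ratio(odf) -> float:
    """Major/minor axis ratio of an ellipse fit to a planar axial histogram.

    The fit uses the axial (orientation) structure tensor
    ``M = sum_i m_i u(phi_i) u(phi_i)^T`` over bin directions; the ratio of
    the square roots of its eigenvalues is the fitted semiaxis ratio.  A
    uniform histogram gives exactly 1; a single-bin histogram is degenerate
    and reports the cap.
    """
    m = np.asarray(odf, dtype=float)
    if m.ndim != 1 or np.any(m < 0) or m.sum() <= 0:
        raise InvalidParameterError("odf must be a non-negative 1-D mass array")
    m = m / m.sum()
    phi = np.radians((np.arange(len(m)) + 0.5) * 180.0 / len(m))
    u = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    M = np.einsum("i,ij,ik->jk", m, u, u)
    w = np.linalg.eigvalsh(M)
    if w[0] <= w[1] / AXIS_RATIO_CAP**2:
        return AXIS_RATIO_CAP
    return float(min(np.sqrt(w[1] / w[0]), AXIS_RATIO_CAP))


def _clip_length_to_box(start, end, lo, hi) -> np.ndarray:
    """Exact length of each segment's intersection with an axis-aligned box."""
    d = end - start
    L = np.linalg.norm(d, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = (lo[None, :] - start) / d
        t1 = (hi[None, :] - start) / d
    t_lo = np.where(np.isnan(t0), -np.inf, np.minimum(t0, t1))
    t_hi = np.where(np.isnan(t0), np.inf, np.maximum(t0, t1))
    # axes with zero direction: inside the slab iff start is inside
    zero = d == 0
    inside = (start >= lo[None, :]) & (start <= hi[None, :])
    t_lo = np.where(zero & ~inside, np.inf, t_lo)
    t_hi = np.where(zero & ~inside, -np.inf, t_hi)
    enter = np.clip(t_lo.max(axis=1), 0.0, 1.0)
    exit_ = np.clip(t_hi.min(axis=1), 0.0, 1.0)
    return np.maximum(exit_ - enter, 0.0) * L


def regional_lengths(network, grid: DomainGrid) -> NetworkMetrics:
    """Vessel length and vascularity per named region (exact geometric clipping).

    Segments straddling a region boundary contribute the clipped share to
    each side, so regional lengths add up to the total length whenever the
    regions tile the domain.
    """
    start, end = _segments_of(network)
    total = float(np.linalg.norm(end - start, axis=1).sum()) if len(start) else 0.0
    region_length, vascularity = {}, {}
    for name, region in grid.regions.items():
        if len(start):
            rl = float(_clip_length_to_box(start, end, region.lo, region.hi).sum())
        else:
            rl = 0.0
        region_length[name] = rl
        vascularity[name] = rl / region.volume
    xy = fit_axis_ratio(planar_odf(network, "xy")) if len(start) else 1.0
    xz = fit_axis_ratio(planar_odf(network, "xz")) if len(start) else 1.0
    return NetworkMetrics(
        total_length=total,
        region_length=region_length,
        vascularity=vascularity,
        xy_axis_ratio=xy,
        xz_axis_ratio=xz,
    )


def plot_z_projection(network, depth_of_field: float = 0.2, z_center: float = None,
                      ax=None):
    """Confocal-style z-projection of the network (optional plotting helper).

    Draws all segments whose midpoint lies within ``depth_of_field`` (mm,
    default 0.2) of ``z_center`` (default: the network's median z).  Returns
    the matplotlib axes.  Not part of the metrics pipeline.
    """
    import matplotlib.pyplot as plt

    start, end = _segments_of(network)
    mid_z = 0.5 * (start[:, 2] + end[:, 2])
    if z_center is None:
        z_center = float(np.median(mid_z))
    keep = np.abs(mid_z - z_center) <= 0.5 * depth_of_field
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for p0, p1 in zip(start[keep], end[keep]):
        ax.plot([p0[0], p1[0]], [p0[1], p1[1]], color="k", lw=0.6)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return ax


def run_single(
    scenario: ScenarioSpec, config: GrowthConfig, seed: int
) -> tuple[VesselNetwork, DomainGrid, NetworkMetrics]:
    """Run one replicate: build, seed, grow, measure."""
    rng = RandomEngine(seed)
    grid = scenario.build_grid()
    config = config.with_(rate_rule=scenario.rate_rule)
    if config.mode == "vector":
        grid.sample_vectors_once(rng)
    network = seed_fragments(
        grid,
        rng,
        per_mm3=scenario.fragments_per_mm3,
        region=scenario.seeding_region,
        z_polarization=scenario.z_polarization,
        init_alpha=config.init_alpha,
    )
    simulate(network, grid, config, rng, scenario.duration)
    return network, grid, regional_lengths(network, grid)


def run_replicates(
    scenario: ScenarioSpec, config: GrowthConfig, base_seed: int = 0
) -> pd.DataFrame:
    """Run the scenario once per replicate seed and tabulate per-seed metrics.

    Replicate seeds are ``base_seed + k`` for ``k`` in ``range(n_seeds)``.
    The frame carries mean/sd summaries and a reproducibility manifest in
    ``attrs``.  A failing seed is recorded with ``ok=False`` and does not
    stop the remaining replicates.
    """
    rows = []
    for k in range(scenario.n_seeds):
        seed = int(base_seed) + k
        try:
            _, _, metrics = run_single(scenario, config, seed)
            row = {"seed": seed, "ok": True}
            row.update(metrics.as_dict())
        except Exception as exc:  # pragma: no cover - defensive
            row = {"seed": seed, "ok": False, "error": str(exc)}
        rows.append(row)
    frame = pd.DataFrame(rows)
    numeric = frame.select_dtypes("number").drop(columns=["seed"])
    frame.attrs["mean"] = numeric.mean().to_dict()
    frame.attrs["sd"] = numeric.std(ddof=1).to_dict() if len(frame) > 1 else {}
    frame.attrs["manifest"] = {
        "family": scenario.family,
        "variant": scenario.variant,
        "seeds": [int(base_seed) + k for k in range(scenario.n_seeds)],
        "duration_days": scenario.duration,
        "mode": config.mode,
        "alpha": config.alpha,
        "dt": config.dt,
    }
    return frame
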