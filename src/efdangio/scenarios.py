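"""Domain construction, field maps, fragment seeding and experiment families.

Three experiment families are provided:

* **uniform_culture** -- a cube of homogeneous collagen at one of three
  anisotropy levels (low/med/high) and one of two densities (3 or 4 mg/mL),
  mirroring hydrogel microvessel cultures.
* **gradient** -- a three-region strip (proximal / middle / distal) in which
  the major EFD radius ramps linearly across the middle region, emulating
  anisotropy gradients found in healing tissue.
* **tacs** -- a tumor / interface / periphery domain in which the thin
  interface carries tumor-associated collagen signatures: TACS-1 raises its
  density, TACS-2 aligns fibrils along the interface, TACS-3 aligns them
  across it (toward the tumor); combinations compose.

Coordinates are right-handed with x the long/gradient axis, origin at the
domain's minimum corner, all positions in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deformation import DeformationGradient, pseudo_deform
from .efd import EFD
from .errors import InvalidParameterError
from .grid import DomainGrid
from .growth import VesselNetwork, growth_directions
from .sampling import RandomEngine, _as_generator, sample_directions

__all__ = [
    "ScenarioSpec",
    "build_uniform_culture",
    "build_gradient",
    "build_tacs",
    "seed_fragments",
    "apply_deformation_field",
    "ANISOTROPY_RADII",
]

#: Semiprincipal radii (x, y, z) per anisotropy level for uniform cultures;
#: the low/high major radii anchor the 1.3-5.0 range used by the gradient maps.
ANISOTROPY_RADII = {
    "low": (1.3, 1.0, 0.5),
    "med": (2.5, 1.0, 0.5),
    "high": (5.0, 1.0, 0.5),
}

#: Near-isotropic baseline radii (exactly degenerate spectra are avoided so
#: eigenvector selection stays well-posed).
BASELINE_RADII = (1.05, 1.0, 0.95)

GRADIENT_BETA1 = (1.3, 5.0)  # major-radius ramp endpoints across the middle region
TACS_INTERFACE_DENSITY = 5.0  # mg/mL (elsewhere 3 mg/mL)
TACS_ALIGNED_RADII = (5.0, 1.0, 0.5)  # sorted radii for aligned interfaces


def _edges(length: float, cell: float) -> np.ndarray:
    n = int(round(length / cell))
    return np.linspace(0.0, length, n + 1)


def build_uniform_culture(
    anisotropy_level: str = "low",
    density: float = 3.0,
    extent: float = 1.0,
    cell_size: float = 0.1,
) -> DomainGrid:
    """Homogeneous cube culture (default 1 mm cube of 0.1 mm cells)."""
    if anisotropy_level not in ANISOTROPY_RADII:
        raise InvalidParameterError(
            f"anisotropy_level must be one of {sorted(ANISOTROPY_RADII)}"
        )
    if density <= 0:
        raise InvalidParameterError("density must be positive")
    e = _edges(extent, cell_size)
    grid = DomainGrid(e, e, e)
    grid.set_uniform_efd(EFD(np.diag(ANISOTROPY_RADII[anisotropy_level])))
    grid.set_uniform_density(float(density))
    grid.add_region("culture", grid.origin, grid.origin + grid.extent)
    return grid


def build_gradient(direction: str = "baseline", cell_size: float = 0.1) -> DomainGrid:
    """Three-region anisotropy-gradient strip, 1.8 x 2.0 x 0.5 mm.

    The proximal and distal flanks are 0.4 mm long and the middle region
    1.0 mm.  In the gradient variants the major radius ramps linearly from
    1.3 to 5.0 (positive) or 5.0 to 1.3 (negative) across the middle, with
    the flanks holding the adjacent end values; the minor radii are fixed at
    1.0 (y) and 0.5 (z).  The baseline is near-isotropic everywhere.
    """
    if direction not in ("baseline", "positive", "negative"):
        raise InvalidParameterError("direction must be baseline/positive/negative")
    x_edges = np.concatenate(
        [_edges(0.4, cell_size), 0.4 + _edges(1.0, cell_size)[1:], 1.4 + _edges(0.4, cell_size)[1:]]
    )
    grid = DomainGrid(x_edges, _edges(2.0, cell_size), _edges(0.5, cell_size))
    grid.add_region("proximal", [0.0, 0.0, 0.0], [0.4, 2.0, 0.5])
    grid.add_region("middle", [0.4, 0.0, 0.0], [1.4, 2.0, 0.5])
    grid.add_region("distal", [1.4, 0.0, 0.0], [1.8, 2.0, 0.5])
    grid.set_uniform_density(3.0)
    if direction == "baseline":
        grid.set_uniform_efd(EFD(np.diag(BASELINE_RADII)))
        return grid
    lo, hi = GRADIENT_BETA1
    if direction == "negative":
        lo, hi = hi, lo
    gp_x = grid.gauss_points()[:, :, 0]
    frac = np.clip((gp_x - 0.4) / 1.0, 0.0, 1.0)
    beta1 = lo + (hi - lo) * frac
    efds = np.zeros((grid.n_cells, 8, 3, 3))
    efds[:, :, 0, 0] = beta1
    efds[:, :, 1, 1] = 1.0
    efds[:, :, 2, 2] = 0.5
    grid.efd = efds
    grid.invalidate_cache()
    return grid


_TACS_CASES = ("baseline", "tacs1", "tacs2", "tacs3", "tacs1_2", "tacs1_3")


def build_tacs(case: str = "baseline", cell_size: float = 0.1) -> DomainGrid:
    """Tumor-invasion domain: periphery / 80 um interface / tumor along y.

    The periphery (1 x 0.8 x 0.6 mm) holds the parent vessels; the tumor
    (1 x 0.8 x 0.6 mm) sits beyond a 1 x 0.08 x 0.6 mm interface whose
    density and alignment encode the requested collagen signature.
    """
    if case not in _TACS_CASES:
        raise InvalidParameterError(f"case must be one of {_TACS_CASES}")
    y_edges = np.concatenate(
        [_edges(0.8, cell_size), [0.84, 0.88], 0.88 + _edges(0.8, cell_size)[1:]]
    )
    grid = DomainGrid(_edges(1.0, cell_size), y_edges, _edges(0.6, cell_size))
    grid.add_region("periphery", [0.0, 0.0, 0.0], [1.0, 0.8, 0.6])
    grid.add_region("interface", [0.0, 0.8, 0.0], [1.0, 0.88, 0.6])
    grid.add_region("tumor", [0.0, 0.88, 0.0], [1.0, 1.68, 0.6])
    grid.set_uniform_efd(EFD(np.diag(BASELINE_RADII)))
    grid.set_uniform_density(3.0)

    iface = grid.regions["interface"].contains(
        0.5 * (np.stack(grid.cell_bounds(np.arange(grid.n_cells)), axis=0).sum(axis=0))
    )
    b1, b2, b3 = TACS_ALIGNED_RADII
    if case in ("tacs1", "tacs1_2", "tacs1_3"):
        grid.density[iface] = TACS_INTERFACE_DENSITY
    if case in ("tacs2", "tacs1_2"):
        grid.efd[iface] = np.diag([b1, b2, b3])  # major axis along the interface (x)
    if case in ("tacs3", "tacs1_3"):
        grid.efd[iface] = np.diag([b2, b1, b3])  # major axis across the interface (y)
    grid.invalidate_cache()
    return grid


def seed_fragments(
    grid: DomainGrid,
    rng,
    n: int = None,
    per_mm3: float = 150.0,
    region: str = None,
    length_median_um: float = 60.0,
    length_sigma_log: float = 0.5,
    z_polarization: float = 0.5,
    init_alpha: float = 0.3,
) -> VesselNetwork:
    """Place parent microvessel fragments and register their tips.

    Fragment centers are uniform in the seeding region (a named region, else
    the whole domain); lengths follow a log-normal stand-in for the measured
    initial-length distribution (median ``length_median_um``); orientations
    are drawn from the seeding EFD ``diag(1, 1, beta3p)`` -- isotropic in the
    XY plane, polarized toward it for ``beta3p < 1``.  Each fragment
    orientation then receives a single guidance rotation (weight
    ``init_alpha``) toward a direction sampled from the local collagen EFD,
    and both ends become active tips.  Fragments poking outside the domain
    are re-placed (up to 100 tries) and finally trimmed.
    """
    if isinstance(rng, int):
        rng = RandomEngine(rng)
    gen = _as_generator(rng)
    if not 0.0 < z_polarization <= 1.0:
        raise InvalidParameterError("z_polarization must lie in (0, 1]")
    if region is not None:
        box = grid.regions[region]
        lo, hi = box.lo, box.hi
        vol = box.volume
    else:
        lo = grid.origin
        hi = grid.origin + grid.extent
        vol = float(np.prod(grid.extent))
    if n is None:
        n = int(round(per_mm3 * vol))
    if n < 0:
        raise InvalidParameterError("fragment count must be non-negative")
    network = VesselNetwork()
    if n == 0:
        return network

    seed_efd = EFD(np.diag([1.0, 1.0, float(z_polarization)]))
    lengths = np.exp(
        gen.normal(np.log(length_median_um * 1e-3), length_sigma_log, size=n)
    )
    dirs = sample_directions(seed_efd, n, gen)
    centers = np.empty((n, 3))
    for i in range(n):
        half = 0.5 * lengths[i] * dirs[i]
        for _ in range(100):
            c = gen.uniform(lo, hi)
            if grid.contains(np.array([c - half, c + half])).all():
                break
        centers[i] = c

    if init_alpha > 0.0:
        radii, axes, _ = grid.interpolate_fields(centers)
        theta = np.empty((n, 3))
        for i in range(n):
            theta[i] = axes[i] @ _principal_frame_sample(radii[i], gen)
        sign = np.sign(np.einsum("ij,ij->i", theta, dirs))
        sign[sign == 0] = 1.0
        dirs = growth_directions(dirs, theta * sign[:, None], init_alpha)

    half = 0.5 * lengths[:, None] * dirs
    p0 = centers - half
    p1 = centers + half
    # trim any residual protrusion to the domain box
    box_lo, box_hi = grid.origin, grid.origin + grid.extent
    p0 = np.clip(p0, box_lo, box_hi)
    p1 = np.clip(p1, box_lo, box_hi)
    segs = network.add_segments(p0, p1, np.full(n, -1), 0.0)
    network.add_tips(p1, dirs, segs)
    network.add_tips(p0, -dirs, segs)
    return network


def _principal_frame_sample(radii: np.ndarray, gen) -> np.ndarray:
    """One rejection sample in a principal frame given sorted radii."""
    inv_sq = 1.0 / radii**2
    bmax = radii[0]
    while True:
        r = gen.uniform(-bmax, bmax, size=3)
        if (r**2 * inv_sq).sum() < 1.0:
            return r / np.linalg.norm(r)


def apply_deformation_field(grid: DomainGrid, F_field) -> DomainGrid:
    """Pseudo-deform every stored EFD by a prescribed deformation-gradient field.

    ``F_field`` may be a single 3x3 matrix, one matrix per cell, or one per
    integration point.  Densities are unchanged.
    """
    F = np.asarray(
        F_field.F if isinstance(F_field, DeformationGradient) else F_field, dtype=float
    )
    if F.shape == (3, 3):
        F = np.broadcast_to(F, (grid.n_cells, 8, 3, 3))
    elif F.shape == (grid.n_cells, 3, 3):
        F = np.broadcast_to(F[:, None], (grid.n_cells, 8, 3, 3))
    elif F.shape != (grid.n_cells, 8, 3, 3):
        raise InvalidParameterError("F_field must be (3,3), (n_cells,3,3) or (n_cells,8,3,3)")
    dets = np.linalg.det(F.reshape(-1, 3, 3)).reshape(grid.n_cells, 8)
    bad = np.argwhere(dets <= 0)
    if len(bad):
        c, k = bad[0]
        raise InvalidParameterError(
            f"deformation gradient with non-positive determinant at cell {c}, point {k}"
        )
    new = np.empty_like(grid.efd)
    for c in range(grid.n_cells):
        for k in range(8):
            new[c, k] = pseudo_deform(EFD(grid.efd[c, k]), DeformationGradient(F[c, k])).tensor
    grid.efd = new
    grid.invalidate_cache()
    return grid


@dataclass
class ScenarioSpec:
    """A named experiment family plus its parameters and replicate seeds."""

    family: str  # uniform_culture | gradient | tacs
    variant: str = "baseline"
    n_seeds: int = 10
    duration: float = None  # days; family default if None
    density: float = 3.0  # uniform_culture only
    extent: float = 1.0  # uniform_culture cube edge, mm
    cell_size: float = 0.1
    fragments_per_mm3: float = 150.0
    z_polarization: float = 0.5
    extra: dict = field(default_factory=dict)

    _FAMILY_DEFAULTS = {
        "uniform_culture": {"duration": 10.0, "region": None, "rate_rule": "sigmoid"},
        "gradient": {"duration": 12.0, "region": "proximal", "rate_rule": "linear"},
        "tacs": {"duration": 10.0, "region": "periphery", "rate_rule": "sigmoid"},
    }

    def __post_init__(self):
        if self.family not in self._FAMILY_DEFAULTS:
            raise InvalidParameterError(f"unknown scenario family {self.family!r}")
        if self.n_seeds < 1:
            raise InvalidParameterError("n_seeds must be >= 1")
        if self.duration is None:
            self.duration = self._FAMILY_DEFAULTS[self.family]["duration"]

    @property
    def seeding_region(self) -> str:
        return self._FAMILY_DEFAULTS[self.family]["region"]

    @property
    def rate_rule(self) -> str:
        return self._FAMILY_DEFAULTS[self.family]["rate_rule"]

    def build_grid(self) -> DomainGrid:
        if self.family == "uniform_culture":
            return build_uniform_culture(
                self.variant, self.density, self.extent, self.cell_size
            )
        if self.family == "gradient":
            return build_gradient(self.variant, self.cell_size)
        return build_tacs(self.variant, self.cell_size)
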