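"""Rectilinear hexahedral domains carrying EFD and density fields.

Fields live at 8 Gauss points per cell (natural coordinates ``+-1/sqrt(3)``).
To interpolate Gauss-point data with nodal-style trilinear shape functions, a
query point's natural coordinates are rescaled by ``sqrt(3)`` and clamped to
``[-1, 1]``, treating the Gauss points as the corners of a shrunken virtual
hexahedron.  EFDs are interpolated by a Log-Euclidean weighted mean; matrix
logarithms of the stored tensors are cached so interpolation reduces to one
batched eigendecomposition per query set.
"""

from __future__ import annotations

import numpy as np

from .efd import EFD
from .errors import InvalidParameterError, OutOfDomainError
from .sampling import _CORNERS, interpolation_weights_batch

__all__ = ["DomainGrid", "Region"]

_GAUSS = _CORNERS / np.sqrt(3.0)


class Region:
    """A named axis-aligned box within the domain."""

    def __init__(self, name: str, lo, hi):
        self.name = name
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)

    @property
    def volume(self) -> float:
        return float(np.prod(self.hi - self.lo))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.all((p >= self.lo - 1e-12) & (p <= self.hi + 1e-12), axis=1)


class DomainGrid:
    """Rectilinear grid of hexahedral cells with per-Gauss-point fields.

    Parameters
    ----------
    x_edges, y_edges, z_edges : 1-D arrays of cell boundaries in mm,
        strictly increasing, origin at the domain's minimum corner.
    """

    def __init__(self, x_edges, y_edges, z_edges):
        self.edges = [np.asarray(e, dtype=float) for e in (x_edges, y_edges, z_edges)]
        for e in self.edges:
            if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
                raise InvalidParameterError("edges must be strictly increasing 1-D arrays")
        self.shape = tuple(len(e) - 1 for e in self.edges)
        self.n_cells = int(np.prod(self.shape))
        self.extent = np.array([e[-1] - e[0] for e in self.edges])
        self.origin = np.array([e[0] for e in self.edges])
        # per-Gauss-point fields
        self.efd = np.tile(np.eye(3), (self.n_cells, 8, 1, 1))
        self.density = np.full((self.n_cells, 8), 3.0)
        self.vectors = None  # legacy mode; filled by sample_vectors_once
        self._log_efd = None
        self.regions: dict[str, Region] = {}

    # -- geometry -----------------------------------------------------------

    def cell_index(self, ixyz) -> np.ndarray:
        ixyz = np.atleast_2d(ixyz)
        nx, ny, _ = self.shape
        return ixyz[:, 0] + nx * (ixyz[:, 1] + ny * ixyz[:, 2])

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Flat cell index containing each point (boundary points -> adjacent cell)."""
        p = np.atleast_2d(points)
        if np.any(~self.contains(p)):
            raise OutOfDomainError("point outside the domain")
        ixyz = np.empty((len(p), 3), dtype=np.int64)
        for a in range(3):
            ixyz[:, a] = np.clip(
                np.searchsorted(self.edges[a], p[:, a], side="right") - 1,
                0,
                self.shape[a] - 1,
            )
        return self.cell_index(ixyz)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        lo = self.origin - 1e-12
        hi = self.origin + self.extent + 1e-12
        return np.all((p >= lo) & (p <= hi), axis=1)

    def cell_bounds(self, cells: np.ndarray):
        """(lo, hi) corner arrays for flat cell indices."""
        cells = np.atleast_1d(cells)
        nx, ny, _ = self.shape
        ix = cells % nx
        iy = (cells // nx) % ny
        iz = cells // (nx * ny)
        lo = np.stack(
            [self.edges[0][ix], self.edges[1][iy], self.edges[2][iz]], axis=1
        )
        hi = np.stack(
            [self.edges[0][ix + 1], self.edges[1][iy + 1], self.edges[2][iz + 1]], axis=1
        )
        return lo, hi

    @property
    def cell_volumes(self) -> np.ndarray:
        dx, dy, dz = (np.diff(e) for e in self.edges)
        # flat convention is x-minor: idx = ix + nx * (iy + ny * iz)
        return (dz[:, None, None] * dy[None, :, None] * dx[None, None, :]).ravel()

    @property
    def min_cell_edge(self) -> float:
        return float(min(np.diff(e).min() for e in self.edges))

    def gauss_points(self) -> np.ndarray:
        """Physical coordinates of all Gauss points, shape (n_cells, 8, 3)."""
        lo, hi = self.cell_bounds(np.arange(self.n_cells))
        half = 0.5 * (hi - lo)
        mid = 0.5 * (hi + lo)
        return mid[:, None, :] + half[:, None, :] * _GAUSS[None, :, :]

    # -- regions ------------------------------------------------------------

    def add_region(self, name: str, lo, hi) -> Region:
        region = Region(name, lo, hi)
        self.regions[name] = region
        return region

    def region_of_cells(self) -> np.ndarray:
        """Region name per cell (by cell center), empty string if unassigned."""
        lo, hi = self.cell_bounds(np.arange(self.n_cells))
        centers = 0.5 * (lo + hi)
        names = np.full(self.n_cells, "", dtype=object)
        for region in self.regions.values():
            names[region.contains(centers)] = region.name
        return names

    # -- fields -------------------------------------------------------------

    def set_uniform_efd(self, efd: EFD) -> None:
        P = efd.tensor if isinstance(efd, EFD) else np.asarray(efd, float)
        self.efd[:] = P
        self._log_efd = None

    def set_uniform_density(self, rho: float) -> None:
        if rho <= 0:
            raise InvalidParameterError("density must be positive")
        self.density[:] = rho
        self._log_efd = self._log_efd  # density does not touch the log cache

    def validate(self) -> None:
        if np.any(self.density <= 0):
            raise InvalidParameterError("density must be positive everywhere")
        w = np.linalg.eigvalsh(self.efd.reshape(-1, 3, 3))
        if np.any(w[:, 0] <= 0):
            raise InvalidParameterError("every integration point must hold a valid EFD")

    @property
    def log_efd(self) -> np.ndarray:
        if self._log_efd is None:
            P = self.efd.reshape(-1, 3, 3)
            w, V = np.linalg.eigh(P)
            if np.any(w[:, 0] <= 0):
                raise InvalidParameterError("non-SPD tensor in EFD field")
            L = np.einsum("nik,nk,njk->nij", V, np.log(w), V)
            self._log_efd = L.reshape(self.efd.shape)
        return self._log_efd

    def invalidate_cache(self) -> None:
        self._log_efd = None

    def write_vtk(self, path) -> None:
        """Export the grid with per-cell density and FA as legacy ASCII VTK."""
        from ._vtk import write_rectilinear_grid

        b = np.sort(np.linalg.eigvalsh(self.efd.mean(axis=1)), axis=1)[:, ::-1]
        fa = np.sqrt(
            0.5
            * ((b[:, 0] - b[:, 1]) ** 2 + (b[:, 1] - b[:, 2]) ** 2 + (b[:, 2] - b[:, 0]) ** 2)
        ) / np.linalg.norm(b, axis=1)
        write_rectilinear_grid(
            path,
            self.edges[0],
            self.edges[1],
            self.edges[2],
            cell_data={"density": self.density.mean(axis=1), "fa": fa},
        )

    def sample_vectors_once(self, rng) -> None:
        """Draw one unit vector per Gauss point from that point's EFD (legacy mode).

        Each integration point is sampled exactly once and never re-sampled.
        """
        from .sampling import sample_direction

        vecs = np.empty((self.n_cells, 8, 3))
        for c in range(self.n_cells):
            for k in range(8):
                vecs[c, k] = sample_direction(EFD(self.efd[c, k]), rng)
        self.vectors = vecs

    # -- interpolation ------------------------------------------------------

    def _weights_for(self, points: np.ndarray, cells: np.ndarray) -> np.ndarray:
        lo, hi = self.cell_bounds(cells)
        xi = 2.0 * (points - lo) / (hi - lo) - 1.0
        xi = np.clip(xi * np.sqrt(3.0), -1.0, 1.0)
        return interpolation_weights_batch(xi)

    def interpolate_fields(self, points: np.ndarray, cells: np.ndarray = None):
        """Interpolated (EFD eigensystem, FA, density) at each query point.

        Returns ``(radii, axes, density)`` with ``radii`` shape (n, 3) sorted
        descending and ``axes`` shape (n, 3, 3) with matching columns.
        """
        points = np.atleast_2d(points)
        if cells is None:
            cells = self.locate(points)
        w = self._weights_for(points, cells)
        L = np.einsum("nk,nkij->nij", w, self.log_efd[cells])
        lam, V = np.linalg.eigh(L)
        radii = np.exp(lam[:, ::-1])
        axes = V[:, :, ::-1]
        rho = (w * self.density[cells]).sum(axis=1)
        return radii, axes, rho

    def interpolate_vectors(
        self, points: np.ndarray, ref_dirs: np.ndarray, cells: np.ndarray = None
    ) -> np.ndarray:
        """Legacy vector-field interpolation at each query point.

        The 8 stored vectors are flipped into the hemisphere of the
        requesting tip's orientation (axial data) before the weighted sum.
        """
        if self.vectors is None:
            raise InvalidParameterError(
                "vector field not initialized; call sample_vectors_once first"
            )
        points = np.atleast_2d(points)
        if cells is None:
            cells = self.locate(points)
        w = self._weights_for(points, cells)
        V = self.vectors[cells]  # (n, 8, 3)
        sign = np.sign(np.einsum("nkj,nj->nk", V, ref_dirs))
        sign[sign == 0] = 1.0
        resultant = np.einsum("nk,nkj->nj", w * sign, V)
        nrm = np.linalg.norm(resultant, axis=1)
        bad = nrm < 1e-12
        if np.any(bad):
            top = np.argmax(w[bad], axis=1)
            resultant[bad] = (V[bad, top] * sign[bad, top][:, None])
            nrm[bad] = 1.0
        return resultant / np.linalg.norm(resultant, axis=1, keepdims=True)
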