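"""Discretized orientation distribution functions on subdivided icosahedra.

An ODF is represented as a normalized mass per triangular facet of an
icosphere.  Facet histograms are count-based: a direction contributes all of
its mass to the single facet whose centroid it is closest to (ties broken by
lowest facet index).  At subdivision level >= 2 facet areas vary by < 7%, so
count-based masses are used directly; an area-corrected density accessor is
provided for glyph rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import InvalidParameterError

__all__ = [
    "SphereMesh",
    "ODFHistogram",
    "build_icosphere",
    "histogram_from_directions",
    "gfa",
    "fisher_rao_distance",
    "read_histogram",
    "write_histogram",
    "write_sphere_vtk",
]


@dataclass(frozen=True)
class SphereMesh:
    """Subdivided icosahedral triangulation of the unit sphere.

    ``vertices`` are unit vectors, ``facets`` index triples into them.
    Level ``L`` has ``10 * 4**L + 2`` vertices and ``20 * 4**L`` facets.
    """

    vertices: np.ndarray
    facets: np.ndarray
    subdivision_level: int
    _centroids: np.ndarray = field(repr=False, default=None)
    _vertex_areas: np.ndarray = field(repr=False, default=None)
    _facet_areas: np.ndarray = field(repr=False, default=None)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_facets(self) -> int:
        return len(self.facets)

    @property
    def facet_centroids(self) -> np.ndarray:
        """Unit-normalized facet centroids, shape (n_facets, 3)."""
        return self._centroids

    @property
    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas (one third of each adjacent facet), normalized to sum 1.

        These serve as quadrature weights for integrals over the sphere
        evaluated at the vertices.
        """
        return self._vertex_areas

    @property
    def facet_areas(self) -> np.ndarray:
        """Flat-triangle facet areas, normalized to sum 1."""
        return self._facet_areas

    def antipode_facets(self) -> np.ndarray:
        """Index of the facet antipodal to each facet (by centroid)."""
        return np.argmax(-self.facet_centroids @ self.facet_centroids.T, axis=1)


def build_icosphere(subdivision_level: int) -> SphereMesh:
    """Build an icosphere mesh at the requested subdivision level."""
    if not isinstance(subdivision_level, (int, np.integer)) or subdivision_level < 0:
        raise InvalidParameterError("subdivision_level must be a non-negative integer")
    m = trimesh.creation.icosphere(subdivisions=int(subdivision_level))
    vertices = np.asarray(m.vertices, dtype=float)
    vertices /= np.linalg.norm(vertices, axis=1, keepdims=True)
    facets = np.asarray(m.faces, dtype=np.int64)
    cent = vertices[facets].mean(axis=1)
    cent /= np.linalg.norm(cent, axis=1, keepdims=True)
    tri = vertices[facets]
    fareas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    vareas = np.zeros(len(vertices))
    np.add.at(vareas, facets.ravel(), np.repeat(fareas / 3.0, 3))
    vareas /= vareas.sum()
    mesh = SphereMesh(
        vertices=vertices,
        facets=facets,
        subdivision_level=int(subdivision_level),
        _centroids=cent,
        _vertex_areas=vareas,
        _facet_areas=fareas / fareas.sum(),
    )
    for arr in (vertices, facets, cent, vareas, mesh._facet_areas):
        arr.setflags(write=False)
    return mesh


@dataclass(frozen=True)
class ODFHistogram:
    """Normalized probability mass over the facets of a :class:`SphereMesh`."""

    mesh: SphereMesh
    mass: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mass, dtype=float)
        if m.shape != (self.mesh.n_facets,):
            raise InvalidParameterError(
                f"mass must have one entry per facet ({self.mesh.n_facets})"
            )
        if np.any(m < 0):
            raise InvalidParameterError("facet masses must be non-negative")
        if abs(m.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(f"facet masses must sum to 1 (got {m.sum()!r})")
        object.__setattr__(self, "mass", m)

    def density(self) -> np.ndarray:
        """Area-corrected density per facet (mass / facet area); for glyph rendering."""
        return self.mass / (self.mesh.facet_areas * 4.0 * np.pi)


def assign_facets(directions: np.ndarray, mesh: SphereMesh) -> np.ndarray:
    """Facet index for each direction: maximum dot product with facet centroids.

    Ties are broken in favor of the lowest facet index (argmax convention).
    """
    d = np.asarray(directions, dtype=float)
    idx = np.empty(len(d), dtype=np.int64)
    # chunked to bound the (n_dirs x n_facets) dot-product workspace
    step = max(1, int(4e6) // max(mesh.n_facets, 1))
    for i in range(0, len(d), step):
        idx[i : i + step] = np.argmax(d[i : i + step] @ mesh.facet_centroids.T, axis=1)
    return idx


def histogram_from_directions(
    directions, mesh: SphereMesh, symmetrize: bool = False, weights=None
) -> ODFHistogram:
    """Bin unit directions to facets and normalize to a probability mass.

    Each direction is assigned to the facet whose centroid is nearest.  With
    ``symmetrize`` the mass is averaged with its antipodal image, appropriate
    for axial data (fibrils, vessel segments).  Optional per-direction
    ``weights`` (e.g. segment lengths) default to equal counts.
    """
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    if d.size == 0:
        raise InvalidParameterError("directions must be non-empty")
    nrm = np.linalg.norm(d, axis=1)
    if np.any(np.abs(nrm - 1.0) > 1e-6):
        raise InvalidParameterError("directions must be unit vectors")
    if weights is None:
        w = np.ones(len(d))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(d),) or np.any(w < 0) or w.sum() <= 0:
            raise InvalidParameterError("weights must be non-negative with positive sum")
    idx = assign_facets(d, mesh)
    mass = np.zeros(mesh.n_facets)
    np.add.at(mass, idx, w)
    mass /= mass.sum()
    if symmetrize:
        anti = mesh.antipode_facets()
        mass = 0.5 * (mass + mass[anti])
        mass /= mass.sum()
    return ODFHistogram(mesh=mesh, mass=mass)


def gfa(odf: ODFHistogram) -> float:
    """Generalized fractional anisotropy of a facet histogram.

    ``GFA = std(mass) / rms(mass)`` over the facet values (population std).
    0 for a uniform histogram; ``sqrt((F-1)/F)`` when a single facet of F
    holds all the mass.
    """
    m = odf.mass if isinstance(odf, ODFHistogram) else np.asarray(odf, float)
    rms = np.sqrt(np.mean(m**2))
    if rms == 0.0:
        raise InvalidParameterError("histogram has no mass")
    return float(m.std() / rms)


def fisher_rao_distance(p: ODFHistogram, q: ODFHistogram) -> float:
    """Fisher-Rao distance between two facet histograms, in degrees.

    ``d = arccos( sum_i sqrt(p_i q_i) )`` -- the arccos of the Bhattacharyya
    coefficient, which for probability mass functions ranges from 0 deg
    (identical) to 90 deg (disjoint supports).
    """
    if p.mesh is not q.mesh and (
        p.mesh.subdivision_level != q.mesh.subdivision_level
        or p.mesh.n_facets != q.mesh.n_facets
    ):
        raise InvalidParameterError("histograms must live on the same mesh")
    bc = float(np.sqrt(p.mass * q.mass).sum())
    return float(np.degrees(np.arccos(np.clip(bc, -1.0, 1.0))))


def write_histogram(path, odf: ODFHistogram) -> None:
    """Write a histogram as a two-column plain-text table (facet index, mass)."""
    with open(path, "w") as fh:
        fh.write(f"# icosphere subdivision level {odf.mesh.subdivision_level}\n")
        fh.write("# facet_index mass\n")
        for i, m in enumerate(odf.mass):
            fh.write(f"{i} {m:.17g}\n")


def read_histogram(path, mesh: SphereMesh = None) -> ODFHistogram:
    """Read a histogram written by :func:`write_histogram`."""
    level = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "subdivision level" in line:
                    level = int(line.rsplit(None, 1)[-1])
                continue
            if line:
                i, m = line.split()
                rows.append((int(i), float(m)))
    if mesh is None:
        if level is None:
            raise InvalidParameterError("histogram file does not record its mesh level")
        mesh = build_icosphere(level)
    mass = np.zeros(mesh.n_facets)
    for i, m in rows:
        mass[i] = m
    return ODFHistogram(mesh=mesh, mass=mass)


def write_sphere_vtk(path, mesh: SphereMesh, facet_scalars=None, scalar_name="mass"):
    """Export a sphere mesh (optionally with per-facet scalars) as legacy ASCII VTK."""
    from ._vtk import write_polydata

    write_polydata(
        path,
        mesh.vertices,
        polygons=mesh.facets,
        cell_scalars=facet_scalars,
        cell_scalar_name=scalar_name,
    )
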