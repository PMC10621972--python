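"""Monte-Carlo sampling of fibril directions and spatial interpolation.

Direction sampling follows the rejection scheme used by the growth model:
uniform points are drawn in the box bounding the EFD ellipsoid in its
principal frame, accepted when they fall inside the ellipsoid, normalized to
unit vectors, and rotated into the global frame.  Uniform-in-volume sampling
followed by normalization gives a directional density proportional to the
cube of the ellipsoid radius along each direction, sharper than the radius
profile itself; this sampler is the model's definition of fibril probing.

Interpolation uses trilinear hexahedral shape functions for scalar fields and
unit-vector fields, and a Log-Euclidean (or optionally affine-invariant)
weighted geodesic mean for EFD tensors, which preserves symmetry and positive
definiteness.
"""

from __future__ import annotations

import numpy as np

from .efd import EFD
from .errors import InvalidParameterError, NumericalError, OutOfDomainError

__all__ = [
    "RandomEngine",
    "sample_direction",
    "sample_directions",
    "natural_coordinates",
    "interpolation_weights",
    "geodesic_interpolate",
    "vector_interpolate",
    "spd_log",
    "spd_exp",
]

_REJECTION_CAP = 10**6


class RandomEngine:
    """Seeded source of reproducible random variates.

    A thin wrapper around :class:`numpy.random.Generator` (PCG64).  An
    identical seed reproduces an identical simulation trajectory end-to-end.
    """

    def __init__(self, seed: int):
        self.seed = int(seed)
        self.generator = np.random.Generator(np.random.PCG64(self.seed))

    def spawn(self, n: int) -> list["RandomEngine"]:
        """Derive ``n`` independent child engines deterministically."""
        children = np.random.SeedSequence(self.seed).spawn(n)
        out = []
        for child in children:
            eng = RandomEngine.__new__(RandomEngine)
            eng.seed = self.seed
            eng.generator = np.random.Generator(np.random.PCG64(child))
            out.append(eng)
        return out

    def uniform(self, low=0.0, high=1.0, size=None):
        return self.generator.uniform(low, high, size)


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, RandomEngine):
        return rng.generator
    if isinstance(rng, np.random.Generator):
        return rng
    raise InvalidParameterError("rng must be a RandomEngine or numpy Generator")


def sample_directions(efd: EFD, n: int, rng, return_stats: bool = False):
    """Draw ``n`` unit fibril directions from an EFD by rejection sampling.

    Proposals are uniform in the cube ``[-max(beta), max(beta)]^3`` in the
    EFD's principal frame and accepted when
    ``r1^2/b1^2 + r2^2/b2^2 + r3^2/b3^2 < 1``.  Accepted points are
    normalized and rotated into the global frame.  With ``return_stats`` a
    ``{'proposals': ..., 'accepted': ...}`` dict is returned as well; the
    expected acceptance rate is the ellipsoid/bounding-cube volume ratio,
    pi/6 for an isotropic EFD.
    """
    gen = _as_generator(rng)
    if not isinstance(efd, EFD):
        efd = EFD(efd)
    radii, axes = efd.radii, efd.axes
    bmax = radii[0]
    inv_sq = 1.0 / radii**2
    out = np.empty((n, 3))
    filled = 0
    proposals = 0
    accepted = 0
    while filled < n:
        if proposals > _REJECTION_CAP * max(n, 1):
            raise NumericalError("rejection sampling iteration cap exceeded")
        batch = max(2 * (n - filled), 16)
        r = gen.uniform(-bmax, bmax, size=(batch, 3))
        proposals += batch
        accept = (r**2 * inv_sq).sum(axis=1) < 1.0
        accepted += int(accept.sum())
        r = r[accept]
        take = min(len(r), n - filled)
        out[filled : filled + take] = r[:take]
        filled += take
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    out = out @ axes.T  # rotate principal-frame directions into the global frame
    if return_stats:
        return out, {"proposals": proposals, "accepted": accepted}
    return out


def sample_direction(efd: EFD, rng) -> np.ndarray:
    """Draw a single unit fibril direction from an EFD."""
    return sample_directions(efd, 1, rng)[0]


def natural_coordinates(cell_bounds, position) -> np.ndarray:
    """Map a position inside an axis-aligned hexahedral cell to [-1, 1]^3.

    ``cell_bounds`` is ``(lo, hi)`` with 3-vectors in mm.  A slack of 1e-9 mm
    is allowed at the faces.
    """
    lo, hi = (np.asarray(b, dtype=float) for b in cell_bounds)
    x = np.asarray(position, dtype=float)
    if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
        raise OutOfDomainError(f"position {x} outside cell [{lo}, {hi}]")
    xi = 2.0 * (x - lo) / (hi - lo) - 1.0
    return np.clip(xi, -1.0, 1.0)


#: Corner sign pattern for trilinear shape functions, shape (8, 3); corner k
#: sits at natural coordinates _CORNERS[k].
_CORNERS = np.array(
    [[sx, sy, sz] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)], dtype=float
)


def interpolation_weights(natural_coords) -> np.ndarray:
    """Trilinear shape-function weights ``N_k = (1/8) prod_i (1 + xi_i c_ki)``.

    Returns 8 non-negative weights summing to 1, ordered by
    z-major/y/x-minor corner (see ``_CORNERS``).
    """
    xi = np.asarray(natural_coords, dtype=float)
    if xi.shape != (3,) or np.any(np.abs(xi) > 1.0 + 1e-12):
        raise InvalidParameterError("natural coordinates must lie in [-1, 1]^3")
    return interpolation_weights_batch(xi[None, :])[0]


def interpolation_weights_batch(xi: np.ndarray) -> np.ndarray:
    """Vectorized trilinear weights for an (n, 3) array of natural coordinates."""
    w = 0.125 * np.prod(1.0 + xi[:, None, :] * _CORNERS[None, :, :], axis=2)
    return w


def spd_log(P: np.ndarray) -> np.ndarray:
    """Matrix logarithm of an SPD matrix via eigendecomposition."""
    w, V = np.linalg.eigh(P)
    if np.any(w <= 0):
        raise InvalidParameterError("matrix is not positive-definite")
    return (V * np.log(w)) @ V.T


def spd_exp(L: np.ndarray) -> np.ndarray:
    """Matrix exponential of a symmetric matrix via eigendecomposition."""
    w, V = np.linalg.eigh(L)
    return (V * np.exp(w)) @ V.T


def geodesic_interpolate(efds, weights, mean: str = "log_euclidean") -> EFD:
    """Weighted geodesic mean of EFDs on the SPD cone.

    The default Log-Euclidean mean is ``exp(sum_i w_i log P_i)``.  The
    affine-invariant Karcher mean is available behind ``mean='affine'`` for
    sensitivity checks (fixed-point iteration).  Both preserve symmetry and
    positive-definiteness for any convex weights.
    """
    w = np.asarray(weights, dtype=float)
    tensors = [e.tensor if isinstance(e, EFD) else np.asarray(e, float) for e in efds]
    if len(tensors) != len(w):
        raise InvalidParameterError("one weight per EFD required")
    if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("weights must be non-negative and sum to 1")
    w = np.clip(w, 0.0, None)
    w = w / w.sum()
    if mean == "log_euclidean":
        L = sum(wi * spd_log(P) for wi, P in zip(w, tensors))
        return EFD(spd_exp(L))
    if mean == "affine":
        M = sum(wi * P for wi, P in zip(w, tensors))
        for _ in range(50):
            ws_, Vs = np.linalg.eigh(M)
            Mh = (Vs * np.sqrt(ws_)) @ Vs.T
            Mih = (Vs * (1.0 / np.sqrt(ws_))) @ Vs.T
            T = sum(wi * spd_log(Mih @ P @ Mih) for wi, P in zip(w, tensors))
            M_new = Mh @ spd_exp(T) @ Mh
            if np.abs(M_new - M).max() < 1e-12 * max(np.abs(M).max(), 1.0):
                M = M_new
                break
            M = M_new
        return EFD(M)
    raise InvalidParameterError(f"unknown mean type {mean!r}")


def vector_interpolate(vectors, weights) -> np.ndarray:
    """Normalized linear weighted sum of unit vectors (legacy comparison mode).

    A perfectly cancelling resultant falls back to the highest-weight input.
    """
    V = np.asarray(vectors, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(V) != len(w):
        raise InvalidParameterError("one weight per vector required")
    if np.any(np.abs(np.linalg.norm(V, axis=1) - 1.0) > 1e-6):
        raise InvalidParameterError("vectors must be unit norm")
    if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("weights must be non-negative and sum to 1")
    resultant = w @ V
    nrm = np.linalg.norm(resultant)
    if nrm < 1e-12:
        return V[np.argmax(w)].copy()
    return resultant / nrm
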