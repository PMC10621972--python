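"""Ellipsoidal fibril distributions (EFDs) as symmetric positive-definite tensors.

An EFD encodes the orientation distribution of collagen fibrils at a material
point as an ellipsoid: the tensor's eigenvalues are the semiprincipal radii
``beta_1 >= beta_2 >= beta_3 > 0`` and its eigenvectors the principal fibril
directions.  Storing the full 3x3 SPD matrix (rather than a (radii, axes)
pair) lets deformation and interpolation act on the tensor directly.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError

__all__ = ["EFD", "efd_from_axes", "spectral_axes", "fractional_anisotropy"]

_SYM_RTOL = 1e-12


class EFD:
    """A 3x3 symmetric positive-definite structure tensor.

    Parameters
    ----------
    tensor : (3, 3) array_like
        Symmetric positive-definite matrix.  The input is symmetrized as
        ``(P + P.T) / 2``; matrices that are not positive-definite after
        symmetrization are rejected.
    """

    __slots__ = ("tensor", "_radii", "_axes")

    def __init__(self, tensor):
        P = np.asarray(tensor, dtype=float)
        if P.shape != (3, 3):
            raise InvalidParameterError(f"EFD tensor must be 3x3, got {P.shape}")
        scale = max(np.abs(P).max(), 1.0)
        if np.abs(P - P.T).max() > 1e-8 * scale:
            raise InvalidParameterError("EFD tensor is not symmetric")
        P = 0.5 * (P + P.T)
        w = np.linalg.eigvalsh(P)
        if w[0] <= 0.0:
            raise InvalidParameterError(
                f"EFD tensor is not positive-definite (min eigenvalue {w[0]:g})"
            )
        self.tensor = P
        self.tensor.setflags(write=False)
        self._radii = None
        self._axes = None

    def _decompose(self):
        if self._radii is None:
            w, V = np.linalg.eigh(self.tensor)
            order = np.argsort(w)[::-1]
            self._radii = w[order]
            self._axes = V[:, order]
        return self._radii, self._axes

    @property
    def radii(self) -> np.ndarray:
        """Semiprincipal radii, sorted descending."""
        return self._decompose()[0]

    @property
    def axes(self) -> np.ndarray:
        """Orthonormal principal axes as matrix columns, matching ``radii``."""
        return self._decompose()[1]

    def radius_along(self, u) -> float:
        """Ellipsoid radius along unit direction ``u`` (in the global frame)."""
        x = np.linalg.solve(self.tensor, np.asarray(u, dtype=float))
        return 1.0 / np.linalg.norm(x)

    def __repr__(self) -> str:  # pragma: no cover
        b = ", ".join(f"{r:.4g}" for r in self.radii)
        return f"EFD(radii=[{b}])"


def efd_from_axes(radii, rotation) -> EFD:
    """Assemble an EFD from semiprincipal radii and an orthonormal axis frame.

    ``P = sum_i beta_i n_i (x) n_i`` with ``n_i`` the columns of ``rotation``.
    """
    radii = np.asarray(radii, dtype=float)
    R = np.asarray(rotation, dtype=float)
    if radii.shape != (3,) or np.any(radii <= 0.0):
        raise InvalidParameterError("radii must be three positive reals")
    if R.shape != (3, 3) or np.abs(R.T @ R - np.eye(3)).max() > 1e-10:
        raise InvalidParameterError("rotation must be a 3x3 orthonormal matrix")
    return EFD(R @ np.diag(radii) @ R.T)


def spectral_axes(efd: EFD):
    """Spectral decomposition of an EFD.

    Returns
    -------
    radii : (3,) ndarray sorted descending
    axes : (3, 3) ndarray, orthonormal columns
    """
    if not isinstance(efd, EFD):
        efd = EFD(efd)
    return efd.radii.copy(), efd.axes.copy()


def fractional_anisotropy(efd) -> float:
    """Fractional anisotropy of an EFD's radii.

    ``FA = sqrt(1/2) * sqrt((b1-b2)^2 + (b2-b3)^2 + (b3-b1)^2) / sqrt(b1^2+b2^2+b3^2)``,
    the population std of the radii over their root mean square.  Invariant
    under rotation of the EFD and uniform scaling of the radii; 0 for an
    isotropic distribution, -> 1 in the uniaxial limit.
    """
    b = efd.radii if isinstance(efd, EFD) else np.sort(np.asarray(efd, float))[::-1]
    num = np.sqrt(0.5 * ((b[0] - b[1]) ** 2 + (b[1] - b[2]) ** 2 + (b[2] - b[0]) ** 2))
    return float(num / np.linalg.norm(b))
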