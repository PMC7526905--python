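"""Ellipsoid-packing shape estimation for a classified crystal.

In normalized cube coordinates the packed bodies are the reference ellipsoids
``x^T R_Z x = 1`` of the detected lattice type Z.  Pulling the quadratic form
back through the normalization ``x = W v`` gives the ellipsoid actually
packed around each molecular centroid in crystal Cartesian coordinates:
``v^T (W^T R_Z W) v = 1``.  Its semi-axes are ``r_i = 1 / sqrt(lambda_i)``
for the eigenvalues ``lambda_i`` of the symmetric matrix ``Q = W^T R_Z W``,
with the eigenvectors as principal directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import LatticeAssignment
from .geometry import CrystalCentroids
from .reference import centroids_per_cell, reference_ellipsoid

__all__ = ["EllipsoidShape", "estimate_ellipsoid", "ellipsoid_volume", "AVOGADRO"]

AVOGADRO = 6.02214076e23  # mol^-1
_NM3_TO_CM3 = 1e-21


@dataclass(frozen=True)
class EllipsoidShape:
    """Radii r1 >= r2 >= r3 (nm), orthonormal principal axes, and the form Q.

    ``axes[:, i]`` is the unit principal direction of radius ``radii[i]`` in
    crystal Cartesian coordinates.  For degenerate radii (spheres, spheroids)
    the eigenbasis is not unique and any orthonormal choice is returned.
    """

    radii: np.ndarray
    axes: np.ndarray
    Q: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        a = np.asarray(self.axes, dtype=float)
        if r.shape != (3,) or np.any(r <= 0) or np.any(np.diff(r) > 1e-12 * r[0]):
            raise ValueError("radii must be three positive values sorted descending")
        if a.shape != (3, 3) or not np.allclose(a.T @ a, np.eye(3), atol=1e-10):
            raise ValueError("principal axes must be orthonormal")
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "axes", a)
        object.__setattr__(self, "Q", np.asarray(self.Q, dtype=float))

    @property
    def volume(self) -> float:
        """Ellipsoid volume (4/3) pi r1 r2 r3 in nm^3."""
        return float(4.0 / 3.0 * np.pi * np.prod(self.radii))


def estimate_ellipsoid(
    crystal: CrystalCentroids, assignment: LatticeAssignment
) -> EllipsoidShape:
    """Shape of the identical ellipsoids packed at the crystal's centroids.

    Requires an assignment to one of P, C, I, F; the reference form of that
    type (with C's distinguished axis on the detected centring axis) is
    pulled back through the stored normalization map ``W``.
    """
    if assignment.is_other:
        raise ValueError("no reference ellipsoid defined for assignment OTHER")
    R = reference_ellipsoid(assignment.assigned, assignment.alpha_side).matrix
    W = assignment.W.matrix
    Q = W.T @ R @ W
    Q = 0.5 * (Q + Q.T)  # symmetrize against round-off
    lam, vec = np.linalg.eigh(Q)  # ascending eigenvalues
    if lam[0] <= 0:
        raise ArithmeticError(
            "non-positive eigenvalue in W^T R W; the normalization map is corrupt"
        )
    radii = 1.0 / np.sqrt(lam)  # ascending lambda -> descending radii
    return EllipsoidShape(radii=radii, axes=vec, Q=Q)


def ellipsoid_volume(shape: EllipsoidShape, per_mole: bool = False) -> float:
    """Ellipsoid volume in nm^3, or in cm^3/mol when ``per_mole`` is set."""
    v = shape.volume
    return v * AVOGADRO * _NM3_TO_CM3 if per_mole else v


def packing_fraction_of(
    crystal: CrystalCentroids, assignment: LatticeAssignment, shape: EllipsoidShape
) -> float:
    """Occupied fraction of the cell: Z * V_ellipsoid / V_cell."""
    z = centroids_per_cell(assignment.assigned)
    return z * shape.volume / crystal.cell.volume
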