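"""Unit-cell algebra and affine normalization of crystal centroid arrangements.

A crystal's unit cell is a parallelepiped given by edge lengths ``a, b, c``
(nm) and angles ``alpha, beta, gamma`` (degrees).  The classification pipeline
normalizes every cell onto a reference cube of side ``alpha_side`` (default
0.1 nm) with the linear map ``W = alpha_side * A^{-1}``, where ``A`` is the
cell matrix; fractional centroid coordinates then become Cartesian points in
the cube.  Because a finite point cloud must represent the infinite periodic
arrangement, centroids sitting on the cell boundary are completed with their
periodic images (a corner centroid contributes all 8 cube corners).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellParameters",
    "AffineMap",
    "CrystalCentroids",
    "MotifCloud",
    "cell_matrix",
    "normalization_map",
    "build_motif_cloud",
]

#: fractional tolerance deciding when a wrapped coordinate sits on the boundary
DEFAULT_BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class CellParameters:
    """Unit-cell lengths (nm) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cell length {name}={getattr(self, name)} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name}={ang} must lie in (0, 180) degrees")

    @property
    def volume(self) -> float:
        """Cell volume in nm^3 (triple product of the cell vectors)."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0.0:
            raise ValueError(
                f"degenerate cell: angles alpha={self.alpha}, beta={self.beta}, "
                f"gamma={self.gamma} give non-positive volume"
            )
        return self.a * self.b * self.c * float(np.sqrt(arg))


@dataclass(frozen=True)
class AffineMap:
    """Invertible linear map (translations are handled by centroid re-centering)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"affine map must be 3x3, got {m.shape}")
        if abs(np.linalg.det(m)) < 1e-300:
            raise ValueError("affine map is singular")
        object.__setattr__(self, "matrix", m)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T

    @property
    def inverse(self) -> "AffineMap":
        return AffineMap(np.linalg.inv(self.matrix))


@dataclass
class CrystalCentroids:
    """Unit cell plus fractional molecular centroid positions.

    ``fractional`` holds one row per molecule in the cell; coordinates are
    wrapped into [0, 1).  ``smiles`` optionally identifies the (single)
    molecular species, ``label`` is free provenance text.
    """

    cell: CellParameters
    fractional: np.ndarray
    smiles: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        f = np.atleast_2d(np.asarray(self.fractional, dtype=float))
        if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] == 0:
            raise ValueError("fractional centroids must be a non-empty (n, 3) array")
        self.fractional = f - np.floor(f)


@dataclass
class MotifCloud:
    """Finite point cloud in the closed cube [0, alpha_side]^3 (nm)."""

    points: np.ndarray
    alpha_side: float
    tol: float = field(default=1e-9)

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.points, dtype=float))
        if p.shape[0] == 0 or p.shape[1] != 3:
            raise ValueError("motif cloud needs at least one 3D point")
        pad = self.tol * self.alpha_side
        if p.min() < -pad or p.max() > self.alpha_side + pad:
            raise ValueError("motif cloud points must lie in the cube [0, alpha]^3")
        self.points = p

    def __len__(self) -> int:
        return self.points.shape[0]


def cell_matrix(cell: CellParameters) -> np.ndarray:
    """Cell matrix ``A`` whose columns are the cell vectors.

    Convention: **a** along x, **b** in the xy-plane.  Cartesian position of a
    fractional coordinate ``f`` is ``A @ f``; ``|det A|`` is the cell volume.
    """
    vol = cell.volume  # raises for degenerate cells
    ca, cb, cg = (np.cos(np.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    sg = np.sin(np.radians(cell.gamma))
    a_vec = np.array([cell.a, 0.0, 0.0])
    b_vec = np.array([cell.b * cg, cell.b * sg, 0.0])
    cz = vol / (cell.a * cell.b * sg)
    c_vec = np.array([cell.c * cb, cell.c * (ca - cb * cg) / sg, cz])
    return np.column_stack([a_vec, b_vec, c_vec])


def normalization_map(cell: CellParameters, alpha_side: float = 0.1) -> AffineMap:
    """Linear map ``W = alpha_side * A^{-1}`` sending the cell onto the cube.

    ``W`` maps each cell vector onto a cube edge, so a fractional coordinate
    ``f`` lands at ``alpha_side * f``.
    """
    if not alpha_side > 0:
        raise ValueError(f"alpha_side={alpha_side} must be > 0")
    return AffineMap(alpha_side * np.linalg.inv(cell_matrix(cell)))


def _wrap_snap(frac: np.ndarray, tol: float) -> np.ndarray:
    """Wrap into [0, 1) and snap coordinates within ``tol`` of 1 down to ~0."""
    w = frac - np.floor(frac)
    w = np.where(w > 1.0 - tol, w - 1.0, w)
    return w


def build_motif_cloud(
    crystal: CrystalCentroids,
    alpha_side: float = 0.1,
    boundary_tol: float = DEFAULT_BOUNDARY_TOL,
) -> MotifCloud:
    """Normalized, boundary-completed centroid cloud of one unit cell.

    Steps: (i) translate all fractional centroids so the first sits at the
    origin (the cloud is translation invariant for true lattice motifs);
    (ii) add periodic images ``f + t``, ``t in {0,1}^3`` restricted to the
    components where ``f`` is within ``boundary_tol`` of 0, so corner / face
    centroids appear with all their images; (iii) scale by ``alpha_side``.

    One centroid per cell yields the 8 cube corners; a body-centre companion
    yields 9 points; one face centre 10; three face centres 14.
    """
    if not alpha_side > 0:
        raise ValueError(f"alpha_side={alpha_side} must be > 0")
    frac = _wrap_snap(crystal.fractional - crystal.fractional[0], boundary_tol)
    images: list[np.ndarray] = []
    for f in frac:
        on_boundary = np.abs(f) <= boundary_tol
        shifts = [np.array([0.0])] * 3
        for axis in range(3):
            if on_boundary[axis]:
                shifts[axis] = np.array([0.0, 1.0])
        for tx in shifts[0]:
            for ty in shifts[1]:
                for tz in shifts[2]:
                    images.append(f + np.array([tx, ty, tz]))
    pts = np.asarray(images) * alpha_side
    pts = _dedupe(pts, tol=boundary_tol * alpha_side)
    return MotifCloud(points=pts, alpha_side=alpha_side, tol=boundary_tol)


def _dedupe(points: np.ndarray, tol: float) -> np.ndarray:
    keep: list[np.ndarray] = []
    for p in points:
        if not any(np.max(np.abs(p - q)) <= tol for q in keep):
            keep.append(p)
    return np.asarray(keep)
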