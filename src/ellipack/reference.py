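"""Reference data for the four basic cubic lattices P, C, I, F.

For each lattice type this module provides the exact motif point set in the
cube of side ``alpha_side`` (corners plus centring positions, with all
periodic boundary images), its persistence diagrams, and the diagonal matrix
of the inscribed identical ellipsoids that realise the densest packing of the
type — spheres for P, I, F and a spheroid for C.  Diagrams are *computed*
from the exact motifs (this keeps multiplicities, which matter for bottleneck
comparison) and cached per (type, centring axis, cube side).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .geometry import MotifCloud
from .persistence import DiagramSet, compute_diagrams

__all__ = [
    "LatticeType",
    "OTHER",
    "ReferenceEllipsoid",
    "motif_points",
    "reference_diagrams",
    "reference_ellipsoid",
    "packing_fraction",
    "centroids_per_cell",
    "fractional_motif",
]

OTHER = "OTHER"

_C_AXES = ("x", "y", "z")
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class LatticeType:
    """One of the basic cubic lattice types P, C, I, F.

    Type C (base-centred) carries the axis perpendicular to the centred face
    pair; P, I, F carry no axis.
    """

    symbol: str
    centering_axis: str | None = None

    def __post_init__(self) -> None:
        if self.symbol not in ("P", "C", "I", "F"):
            raise ValueError(f"lattice type must be P, C, I or F, got {self.symbol!r}")
        if self.symbol == "C":
            if self.centering_axis not in _C_AXES:
                raise ValueError("type C requires a centering_axis in {'x','y','z'}")
        elif self.centering_axis is not None:
            raise ValueError(f"type {self.symbol} does not take a centering axis")

    def __str__(self) -> str:
        return self.symbol


P = LatticeType("P")
I = LatticeType("I")  # noqa: E741 - crystallographic symbol
F = LatticeType("F")
C_X, C_Y, C_Z = (LatticeType("C", ax) for ax in _C_AXES)


def _as_type(t) -> LatticeType:
    if isinstance(t, LatticeType):
        return t
    if t == "C":
        return C_Z
    return LatticeType(str(t))


@dataclass(frozen=True)
class ReferenceEllipsoid:
    """Diagonal quadratic form of the packed ellipsoid, in cube coordinates.

    Diagonal entries are ``r_i^{-2}`` (nm^-2); the ellipsoid is
    ``x^T R x = 1``.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3) or np.any(m != np.diag(np.diag(m))) or np.any(np.diag(m) <= 0):
            raise ValueError("reference ellipsoid matrix must be diagonal positive")
        object.__setattr__(self, "matrix", m)

    @property
    def radii(self) -> np.ndarray:
        return 1.0 / np.sqrt(np.diag(self.matrix))


def centroids_per_cell(lattice: LatticeType | str) -> int:
    """Number of lattice points (molecules) per conventional cubic cell."""
    return {"P": 1, "C": 2, "I": 2, "F": 4}[str(_as_type(lattice))]


def fractional_motif(lattice: LatticeType | str) -> np.ndarray:
    """Fractional positions of the motif inside one cell (without images)."""
    t = _as_type(lattice)
    if t.symbol == "P":
        return np.zeros((1, 3))
    if t.symbol == "I":
        return np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]])
    if t.symbol == "F":
        return np.array(
            [[0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
        )
    face = np.full(3, 0.5)
    face[_AXIS_INDEX[t.centering_axis]] = 0.0
    return np.vstack([np.zeros(3), face])


def motif_points(lattice: LatticeType | str, alpha_side: float = 0.1) -> MotifCloud:
    """Exact finite motif cloud: corners plus centring positions with images.

    P: the 8 cube corners; C: corners + both centres of the centred face pair
    (10 points); I: corners + body centre (9); F: corners + all 6 face
    centres (14).
    """
    if not alpha_side > 0:
        raise ValueError(f"alpha_side={alpha_side} must be > 0")
    t = _as_type(lattice)
    corners = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], float)
    extras: list[np.ndarray] = []
    for f in fractional_motif(t)[1:]:
        zero = np.isclose(f, 0.0)
        shifts = [np.array([0.0, 1.0]) if zero[ax] else np.array([0.0]) for ax in range(3)]
        for tx in shifts[0]:
            for ty in shifts[1]:
                for tz in shifts[2]:
                    extras.append(f + np.array([tx, ty, tz]))
    pts = np.vstack([corners] + [np.asarray(extras)] if extras else [corners])
    return MotifCloud(points=pts * alpha_side, alpha_side=alpha_side)


@lru_cache(maxsize=64)
def _cached_diagrams(symbol: str, axis: str | None, alpha_side: float) -> DiagramSet:
    return compute_diagrams(motif_points(LatticeType(symbol, axis), alpha_side))


def reference_diagrams(lattice: LatticeType | str, alpha_side: float = 0.1) -> DiagramSet:
    """Persistence diagrams of the exact motif, computed once and cached.

    The three centring axes of type C give congruent motifs, hence identical
    diagrams; the cache therefore keys C on its axis only for exactness of
    the motif, not because the diagrams differ.
    """
    t = _as_type(lattice)
    return _cached_diagrams(t.symbol, t.centering_axis, float(alpha_side))


def reference_ellipsoid(
    lattice: LatticeType | str, alpha_side: float = 0.1
) -> ReferenceEllipsoid:
    """Quadratic form of the identical ellipsoids packed at the motif points.

    Radii in cube coordinates: P -> (α/2)·(1,1,1); I -> (√3α/4)·(1,1,1)
    (contact along the body diagonal); F -> (√2α/4)·(1,1,1) (contact along
    face diagonals); C -> (√2α/4, √2α/4, α/2) with the α/2 semi-axis on the
    centring axis.
    """
    if not alpha_side > 0:
        raise ValueError(f"alpha_side={alpha_side} must be > 0")
    t = _as_type(lattice)
    a = alpha_side
    if t.symbol == "P":
        radii = np.full(3, a / 2.0)
    elif t.symbol == "I":
        radii = np.full(3, np.sqrt(3.0) * a / 4.0)
    elif t.symbol == "F":
        radii = np.full(3, np.sqrt(2.0) * a / 4.0)
    else:
        radii = np.full(3, np.sqrt(2.0) * a / 4.0)
        radii[_AXIS_INDEX[t.centering_axis]] = a / 2.0
    return ReferenceEllipsoid(np.diag(radii**-2.0))


def packing_fraction(lattice: LatticeType | str) -> float:
    """Fraction of the cell occupied by the packed reference ellipsoids.

    ``Z · (4/3)π r1 r2 r3 / α³`` with Z molecules per cell; independent of α.
    π/√18 ≈ 0.74048 for type F (closest packing).
    """
    t = _as_type(lattice)
    r = reference_ellipsoid(t, 1.0).radii
    return float(centroids_per_cell(t) * (4.0 / 3.0) * np.pi * np.prod(r))
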