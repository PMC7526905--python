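"""Persistent homology of small 3D point clouds under ball growth, and the
bottleneck distance between persistence diagrams.

The filtration is the exact Čech filtration on the **ball-radius** scale: a
simplex enters the complex at the radius of the minimal enclosing ball of its
vertices, so two points at distance ``d`` merge at ``d/2``.  (A Vietoris–Rips
filtration would report ``d`` instead and does not reproduce the analytic
diagrams of the cubic-lattice motifs.)  Simplices are enumerated up to
dimension 3, which computes homology exactly in degrees q = 0, 1, 2 — the
three degrees with geometric meaning in 3D (components, rings, cavities).

Minimal enclosing balls are computed exactly per support subset, so the
highly symmetric (cocircular / cospherical) motif configurations need no
symmetry-breaking perturbation.

Intended for motif-sized clouds (tens of points); complexity grows as
``n choose 4``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

__all__ = [
    "PersistenceDiagram",
    "DiagramSet",
    "compute_diagrams",
    "bottleneck_distance",
    "cech_filtration_value",
]

# relative tolerance for ball-containment tests and zero-persistence culling
_REL_TOL = 1e-9


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (birth, death) ball radii (nm) for one homology degree.

    ``death`` may be ``numpy.inf`` (essential classes).  Pairs with zero
    persistence are culled at construction.
    """

    dimension: int
    pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        if self.dimension not in (0, 1, 2):
            raise ValueError(f"homology degree must be 0, 1 or 2, got {self.dimension}")
        p = np.asarray(self.pairs, dtype=float).reshape(-1, 2)
        if p.size and not np.all((p[:, 1] > p[:, 0]) | np.isinf(p[:, 1])):
            raise ValueError("every death must exceed its birth (or be inf)")
        if p.size and p[:, 0].min() < 0:
            raise ValueError("births must be non-negative")
        order = np.lexsort((p[:, 1], p[:, 0])) if p.size else np.array([], dtype=int)
        object.__setattr__(self, "pairs", p[order])

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @property
    def finite(self) -> np.ndarray:
        return self.pairs[np.isfinite(self.pairs[:, 1])]

    @property
    def essential_births(self) -> np.ndarray:
        return self.pairs[np.isinf(self.pairs[:, 1]), 0]

    def distinct(self, tol: float = 1e-9) -> np.ndarray:
        """Deduplicated (birth, death) values, for comparison with analytic lists."""
        out: list[np.ndarray] = []
        for row in self.pairs:
            if not any(
                np.allclose(row, kept, atol=tol, equal_nan=False)
                or (np.isinf(row[1]) and np.isinf(kept[1]) and abs(row[0] - kept[0]) <= tol)
                for kept in out
            ):
                out.append(row)
        return np.asarray(out).reshape(-1, 2)


@dataclass(frozen=True)
class DiagramSet:
    """The three diagrams q = 0, 1, 2 of one point cloud."""

    d0: PersistenceDiagram
    d1: PersistenceDiagram
    d2: PersistenceDiagram
    n_points: int = 0

    def __getitem__(self, q: int) -> PersistenceDiagram:
        try:
            return (self.d0, self.d1, self.d2)[q]
        except IndexError:
            raise KeyError(f"no diagram for q={q}") from None


# ---------------------------------------------------------------------------
# Čech filtration values (minimal enclosing ball radii), vectorized by arity
# ---------------------------------------------------------------------------


def _pair_radii(pts: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    return d / 2.0


def _triangle_radii(pts: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Minimal enclosing ball radius of each triangle.

    Half the longest edge when the triangle is right/obtuse (the opposite
    vertex lies inside that diametral ball), else the circumradius.
    """
    A, B, C = pts[tris[:, 0]], pts[tris[:, 1]], pts[tris[:, 2]]
    ab = np.linalg.norm(A - B, axis=1)
    bc = np.linalg.norm(B - C, axis=1)
    ca = np.linalg.norm(C - A, axis=1)
    edges = np.stack([ab, bc, ca], axis=1)
    longest = edges.max(axis=1)
    sq = edges**2
    obtuse = 2.0 * sq.max(axis=1) >= sq.sum(axis=1) - _REL_TOL * longest**2
    # circumradius R = abc / (4 * area); area via cross product
    cross = np.cross(B - A, C - A)
    area2 = np.linalg.norm(cross, axis=1)  # = 2 * area
    with np.errstate(divide="ignore", invalid="ignore"):
        circ = ab * bc * ca / (2.0 * area2)
    return np.where(obtuse, longest / 2.0, circ)


def _circumcenters_tri(A: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Circumcenters of (possibly degenerate) triangles; NaN rows when collinear."""
    a = B - A
    b = C - A
    axb = np.cross(a, b)
    denom = 2.0 * np.einsum("ij,ij->i", axb, axb)
    num = np.cross(
        np.einsum("ij,ij->i", b, b)[:, None] * a - np.einsum("ij,ij->i", a, a)[:, None] * b,
        axb,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        return A - num / denom[:, None]


def _tetra_radii(pts: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Minimal enclosing ball radius of each 4-point subset.

    The optimal ball is supported by 2, 3 or 4 of the points; candidates are
    the six diametral pair balls, the four triangle circumballs and the
    circumsphere, filtered by containment of all four points.
    """
    m = quads.shape[0]
    P = pts[quads]  # (m, 4, 3)
    best = np.full(m, np.inf)

    def consider(centers: np.ndarray, radii: np.ndarray) -> None:
        nonlocal best
        ok = np.isfinite(radii) & np.isfinite(centers).all(axis=1)
        dist = np.linalg.norm(P - centers[:, None, :], axis=2).max(axis=1)
        ok &= dist <= radii * (1.0 + _REL_TOL) + 1e-300
        best = np.where(ok & (radii < best), radii, best)

    for i, j in combinations(range(4), 2):
        centers = 0.5 * (P[:, i] + P[:, j])
        radii = 0.5 * np.linalg.norm(P[:, i] - P[:, j], axis=1)
        consider(centers, radii)
    for tri in combinations(range(4), 3):
        A, B, C = P[:, tri[0]], P[:, tri[1]], P[:, tri[2]]
        centers = _circumcenters_tri(A, B, C)
        radii = np.linalg.norm(centers - A, axis=1)
        consider(centers, radii)
    # circumsphere: solve 2 (p_i - p_0) . c = |p_i|^2 - |p_0|^2, i = 1..3
    M = 2.0 * (P[:, 1:] - P[:, :1])  # (m, 3, 3)
    rhs = np.einsum("mij,mij->mi", P[:, 1:], P[:, 1:]) - np.einsum(
        "mj,mj->m", P[:, 0], P[:, 0]
    )[:, None]
    dets = np.linalg.det(M)
    solvable = np.abs(dets) > 1e-30
    centers = np.full((m, 3), np.nan)
    if solvable.any():
        centers[solvable] = np.linalg.solve(M[solvable], rhs[solvable, :, None])[:, :, 0]
    consider(centers, np.linalg.norm(centers - P[:, 0], axis=1))
    return best


def cech_filtration_value(points: np.ndarray, simplex: tuple[int, ...]) -> float:
    """Čech filtration value (minimal enclosing ball radius) of one simplex."""
    pts = np.asarray(points, dtype=float)
    idx = np.asarray(simplex, dtype=int)
    if idx.size == 1:
        return 0.0
    if idx.size == 2:
        return float(_pair_radii(pts, idx[None, :])[0])
    if idx.size == 3:
        return float(_triangle_radii(pts, idx[None, :])[0])
    if idx.size == 4:
        return float(_tetra_radii(pts, idx[None, :])[0])
    raise ValueError("simplices of dimension > 3 are not supported")


# ---------------------------------------------------------------------------
# Persistence via boundary-matrix reduction over Z/2
# ---------------------------------------------------------------------------


def compute_diagrams(cloud) -> DiagramSet:
    """Persistence diagrams (q = 0, 1, 2) of a motif cloud.

    Accepts a :class:`~ellipack.geometry.MotifCloud` or a plain (n, 3) array.
    All values are ball radii in the units of the input coordinates.
    """
    pts = np.asarray(getattr(cloud, "points", cloud), dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    if n == 0:
        raise ValueError("empty point cloud")
    scale = max(float(np.abs(pts).max()), 1.0e-300)
    if n > 1:
        from scipy.spatial.distance import pdist

        if pdist(pts).min() <= _REL_TOL * scale:
            raise ValueError("duplicate points in cloud (multiplicity undefined)")

    simplices: list[tuple[int, ...]] = [(i,) for i in range(n)]
    values: list[np.ndarray] = [np.zeros(n)]
    if n >= 2:
        pairs = np.array(list(combinations(range(n), 2)), dtype=int)
        simplices += [tuple(s) for s in pairs]
        values.append(_pair_radii(pts, pairs))
    if n >= 3:
        tris = np.array(list(combinations(range(n), 3)), dtype=int)
        simplices += [tuple(s) for s in tris]
        values.append(_triangle_radii(pts, tris))
    if n >= 4:
        quads = np.array(list(combinations(range(n), 4)), dtype=int)
        simplices += [tuple(s) for s in quads]
        values.append(_tetra_radii(pts, quads))
    vals = np.concatenate(values)

    # enforce exact filtration monotonicity: independent miniball formulas can
    # disagree in the last ulp, putting a coface a hair before its face
    value_of: dict[tuple[int, ...], float] = {}
    for k, s in enumerate(simplices):  # list is ordered by dimension
        v = float(vals[k])
        if len(s) > 1:
            for drop in range(len(s)):
                v = max(v, value_of[s[:drop] + s[drop + 1 :]])
        value_of[s] = v
        vals[k] = v

    dims = np.fromiter((len(s) - 1 for s in simplices), dtype=int, count=len(simplices))
    order = np.lexsort((dims, vals))  # faces precede cofaces: equal value -> lower dim first
    index_of = {simplices[j]: pos for pos, j in enumerate(order)}

    # column reduction with int bitmasks; pivot = highest set row bit
    pivot_owner: dict[int, int] = {}
    columns: dict[int, int] = {}
    births: dict[int, tuple[int, float]] = {}  # row -> (dim, value)
    pairs_out: list[tuple[int, float, float]] = []
    positive = [True] * len(order)

    for pos, j in enumerate(order):
        s = simplices[j]
        dim = len(s) - 1
        births[pos] = (dim, float(vals[j]))
        if dim == 0:
            continue
        col = 0
        for k in range(len(s)):
            face = s[:k] + s[k + 1 :]
            col ^= 1 << index_of[face]
        while col:
            piv = col.bit_length() - 1
            owner = pivot_owner.get(piv)
            if owner is None:
                break
            col ^= columns[owner]
        if col:
            piv = col.bit_length() - 1
            pivot_owner[piv] = pos
            columns[pos] = col
            positive[pos] = False
            positive[piv] = True  # paired: piv created the class this kills
            bdim, bval = births[piv]
            pairs_out.append((bdim, bval, float(vals[j])))
            births.pop(piv)

    # unpaired (essential) classes: creators never killed
    essential: list[tuple[int, float]] = []
    killed = set(pivot_owner)
    for pos in range(len(order)):
        dim, val = births.get(pos, (None, None))
        if dim is None or pos in killed:
            continue
        if pos in columns:  # negative column (kills something)
            continue
        if dim <= 2:
            essential.append((dim, val))

    by_q: dict[int, list[list[float]]] = {0: [], 1: [], 2: []}
    for dim, b, d in pairs_out:
        if dim <= 2 and d > b + _REL_TOL * scale:
            by_q[dim].append([b, d])
    for dim, b in essential:
        by_q[dim].append([b, np.inf])
    return DiagramSet(
        d0=PersistenceDiagram(0, np.asarray(by_q[0]).reshape(-1, 2)),
        d1=PersistenceDiagram(1, np.asarray(by_q[1]).reshape(-1, 2)),
        d2=PersistenceDiagram(2, np.asarray(by_q[2]).reshape(-1, 2)),
        n_points=n,
    )


# ---------------------------------------------------------------------------
# Bottleneck distance
# ---------------------------------------------------------------------------


def _diag_cost(pairs: np.ndarray) -> np.ndarray:
    """L-infinity distance of each finite pair to the diagonal: (d - b) / 2."""
    return (pairs[:, 1] - pairs[:, 0]) / 2.0


def _feasible(cost: np.ndarray, dx: np.ndarray, dy: np.ndarray, c: float) -> bool:
    """Perfect matching at threshold c in the augmented bipartite graph.

    Left nodes: X points then Y-diagonal proxies; right nodes: Y points then
    X-diagonal slots.  Proxy-to-slot edges are free, so unmatched points pay
    their own diagonal cost.
    """
    n, m = dx.size, dy.size
    rows, cols = [], []
    xi, yj = np.nonzero(cost <= c)
    rows += list(xi)
    cols += list(yj)
    for i in np.nonzero(dx <= c)[0]:  # X_i may retire to the diagonal
        rows.append(i)
        cols.append(m + i)
    for j in np.nonzero(dy <= c)[0]:  # Y_j may be created from the diagonal
        rows.append(n + j)
        cols.append(j)
    # proxies pair freely with slots
    for i in range(n):
        for j in range(m):
            rows.append(n + j)
            cols.append(m + i)
    g = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n + m, n + m))
    match = maximum_bipartite_matching(g, perm_type="column")
    return int((match >= 0).sum()) == n + m


def bottleneck_distance(X: PersistenceDiagram, Y: PersistenceDiagram) -> float:
    """Bottleneck distance between two diagrams of the same homology degree.

    Infimum over partial matchings of the sup L-infinity transport cost;
    unmatched finite points pay their distance to the diagonal.  Essential
    (infinite-death) classes must be matched to each other at cost
    ``|b_X - b_Y|``; the distance is ``inf`` when the essential counts differ.
    """
    if X.dimension != Y.dimension:
        raise ValueError(
            f"cannot compare diagrams of degrees {X.dimension} and {Y.dimension}"
        )
    ex, ey = np.sort(X.essential_births), np.sort(Y.essential_births)
    if ex.size != ey.size:
        return float("inf")
    c_inf = float(np.abs(ex - ey).max()) if ex.size else 0.0

    fx, fy = X.finite, Y.finite
    if fx.shape[0] == 0 and fy.shape[0] == 0:
        return c_inf
    dx, dy = _diag_cost(fx), _diag_cost(fy)
    if fx.shape[0] and fy.shape[0]:
        cost = np.abs(fx[:, None, :] - fy[None, :, :]).max(axis=2)
    else:
        cost = np.empty((fx.shape[0], fy.shape[0]))
    candidates = np.unique(np.concatenate([cost.ravel(), dx, dy, [0.0, c_inf]]))
    lo, hi = 0, candidates.size - 1
    # the largest candidate (match everything to the diagonal or anywhere) is feasible
    while lo < hi:
        mid = (lo + hi) // 2
        if _feasible(cost, dx, dy, candidates[mid]):
            hi = mid
        else:
            lo = mid + 1
    return max(c_inf, float(candidates[lo]))
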