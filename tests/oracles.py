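"""Independent brute-force oracles used by the test suite only."""

from itertools import permutations

import numpy as np
from scipy.optimize import minimize
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform


def mst_death_radii(points):
    """q=0 finite death radii: half the minimum-spanning-tree edge lengths."""
    d = squareform(pdist(points))
    mst = minimum_spanning_tree(d).toarray()
    return np.sort(mst[mst > 0]) / 2.0


def minimax_ball_radius(points, restarts=8, seed=0):
    """Minimal enclosing ball radius by direct minimax optimization."""
    pts = np.asarray(points, float)
    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [pts.mean(axis=0)] + [
        pts.mean(axis=0) + rng.normal(0, 0.2 * (np.ptp(pts) + 1e-9), 3) for _ in range(restarts)
    ]
    for x0 in starts:
        res = minimize(
            lambda c: np.max(np.linalg.norm(pts - c, axis=1)),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-12, "maxiter": 5000},
        )
        best = min(best, res.fun)
    return best


def bottleneck_brute(X_pairs, Y_pairs):
    """Bottleneck distance by enumerating all partial matchings.

    Each X point is matched to a distinct Y point or deleted to the diagonal
    (cost (d-b)/2); unmatched Y points are deleted likewise.  Only feasible
    for a handful of off-diagonal points.  Infinite-death points must pair
    with each other by sorted birth.
    """
    X = np.asarray(X_pairs, float).reshape(-1, 2)
    Y = np.asarray(Y_pairs, float).reshape(-1, 2)
    xi, yi = np.isinf(X[:, 1]), np.isinf(Y[:, 1])
    if xi.sum() != yi.sum():
        return np.inf
    c_inf = 0.0
    if xi.any():
        c_inf = np.max(np.abs(np.sort(X[xi, 0]) - np.sort(Y[yi, 0])))
    FX, FY = X[~xi], Y[~yi]
    n, m = len(FX), len(FY)
    dx = (FX[:, 1] - FX[:, 0]) / 2.0
    dy = (FY[:, 1] - FY[:, 0]) / 2.0
    best = np.inf
    # choose which X points match (ordered subset of Y targets via permutations
    # of Y indices padded with "diagonal" sentinels)
    sentinels = [-1] * n
    for assign in set(permutations(list(range(m)) + sentinels, n)):
        cost = 0.0
        used = set()
        for i, j in enumerate(assign):
            if j == -1:
                cost = max(cost, dx[i])
            else:
                used.add(j)
                cost = max(cost, np.max(np.abs(FX[i] - FY[j])))
        for j in range(m):
            if j not in used:
                cost = max(cost, dy[j])
        best = min(best, cost)
    if n == 0:
        best = float(dy.max()) if m else 0.0
    return max(best, c_inf)


def random_diagram(rng, max_points=6, scale=1.0, with_inf=False):
    """Random finite diagram for oracle comparisons."""
    k = int(rng.integers(0, max_points + 1))
    b = rng.uniform(0, scale, k)
    d = b + rng.uniform(1e-3, scale, k)
    pairs = np.column_stack([b, d]) if k else np.empty((0, 2))
    if with_inf:
        pairs = np.vstack([pairs, [rng.uniform(0, scale), np.inf]])
    return pairs
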