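"""Assign a crystal's centroid arrangement to a cubic lattice type.

The normalized, boundary-completed centroid cloud of the crystal is compared
with the reference motif of each type by the bottleneck distance between
persistence diagrams, aggregated over homology degrees q = 0, 1, 2.  The
crystal is assigned the best-scoring type when that score falls below the
acceptance threshold ``epsilon`` (0.001 nm by default), else ``OTHER``.

The default aggregation is the *minimum* over q, which accepts a match as
soon as any single homology degree matches; a strict ``max`` mode (all three
degrees must match) is available and is the safer choice for screening
negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AffineMap, CrystalCentroids, MotifCloud, build_motif_cloud, normalization_map
from .persistence import bottleneck_distance, compute_diagrams
from .reference import (
    OTHER,
    C_X,
    C_Y,
    C_Z,
    F,
    I,
    LatticeType,
    P,
    motif_points,
    reference_diagrams,
)

__all__ = ["LatticeAssignment", "classify", "DEFAULT_ALPHA_SIDE", "DEFAULT_EPSILON"]

DEFAULT_ALPHA_SIDE = 0.1  # nm, cube side after normalization
DEFAULT_EPSILON = 0.001  # nm, acceptable bottleneck error

# a one-cell cloud larger than this cannot come from a cubic motif: the
# largest reference has 14 points and a single extra centroid contributes at
# most 8 corner images
_MAX_MOTIF_POINTS = 22

_TYPE_ORDER = ("P", "C", "I", "F")
_EXACT_TIE = 1e-12


@dataclass
class LatticeAssignment:
    """Classification result with full per-type audit scores.

    ``scores`` maps type symbol to the aggregated bottleneck distance (nm);
    ``per_q`` maps type symbol to the three per-degree distances.  ``W`` is
    the normalization map used, needed downstream for ellipsoid estimation.
    """

    assigned: LatticeType | str
    scores: dict[str, float]
    per_q: dict[str, tuple[float, float, float]]
    epsilon: float
    alpha_side: float
    aggregate: str
    W: AffineMap
    cloud_size: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def is_other(self) -> bool:
        return isinstance(self.assigned, str) and self.assigned == OTHER

    @property
    def symbol(self) -> str:
        return OTHER if self.is_other else str(self.assigned)


def _detect_c_axis(cloud: MotifCloud) -> LatticeType:
    """Pick the C orientation whose exact motif is geometrically closest.

    The three centring orientations are congruent, so their persistence
    diagrams coincide; the axis is decided by the directed Hausdorff distance
    from the reference motif to the observed cloud.
    """
    best, best_d = C_Z, np.inf
    for cand in (C_X, C_Y, C_Z):
        ref = motif_points(cand, cloud.alpha_side).points
        d = max(
            np.min(np.linalg.norm(cloud.points[None, :, :] - ref[:, None, :], axis=2), axis=1).max(),
            np.min(np.linalg.norm(ref[None, :, :] - cloud.points[:, None, :], axis=2), axis=1).max(),
        )
        if d < best_d - _EXACT_TIE:
            best, best_d = cand, d
    return best


def classify(
    crystal: CrystalCentroids,
    alpha_side: float = DEFAULT_ALPHA_SIDE,
    epsilon: float = DEFAULT_EPSILON,
    aggregate: str = "min",
) -> LatticeAssignment:
    """Classify a crystal's centroid arrangement as P, C, I, F or OTHER.

    Parameters
    ----------
    crystal:
        Unit cell plus fractional centroids.
    alpha_side:
        Side of the normalization cube in nm.
    epsilon:
        Acceptance threshold on the aggregated bottleneck distance (nm).
    aggregate:
        ``"min"`` (a match in any homology degree suffices, the permissive
        criterion) or ``"max"`` (all three degrees must match).
    """
    if not epsilon > 0:
        raise ValueError(f"epsilon={epsilon} must be > 0")
    if aggregate not in ("min", "max"):
        raise ValueError(f"aggregate must be 'min' or 'max', got {aggregate!r}")
    W = normalization_map(crystal.cell, alpha_side)
    cloud = build_motif_cloud(crystal, alpha_side)
    notes: list[str] = []

    if len(cloud) > _MAX_MOTIF_POINTS:
        notes.append(f"cloud of {len(cloud)} points exceeds any cubic motif; skipped diagrams")
        inf3 = (np.inf, np.inf, np.inf)
        return LatticeAssignment(
            assigned=OTHER,
            scores={s: np.inf for s in _TYPE_ORDER},
            per_q={s: inf3 for s in _TYPE_ORDER},
            epsilon=epsilon,
            alpha_side=alpha_side,
            aggregate=aggregate,
            W=W,
            cloud_size=len(cloud),
            notes=notes,
        )

    diagrams = compute_diagrams(cloud)
    scores: dict[str, float] = {}
    per_q: dict[str, tuple[float, float, float]] = {}
    for symbol in _TYPE_ORDER:
        ref = reference_diagrams(symbol, alpha_side)
        dq = tuple(bottleneck_distance(diagrams[q], ref[q]) for q in range(3))
        per_q[symbol] = dq
        if aggregate == "max":
            scores[symbol] = float(max(dq))
        else:
            # minimum over informative degrees only: an empty-vs-empty
            # comparison carries no topological evidence and must not count
            # as a perfect match
            informative = [
                dq[q] for q in range(3) if len(diagrams[q]) or len(ref[q])
            ]
            scores[symbol] = float(min(informative)) if informative else float(max(dq))

    best_symbol = None
    best_score = np.inf
    for symbol in _TYPE_ORDER:  # fixed order breaks exact ties P, C, I, F
        if scores[symbol] < best_score - _EXACT_TIE:
            best_symbol, best_score = symbol, scores[symbol]
    if best_score >= epsilon:
        assigned: LatticeType | str = OTHER
    elif best_symbol == "C":
        assigned = _detect_c_axis(cloud)
        notes.append(f"C centring axis detected: {assigned.centering_axis}")
    else:
        assigned = {"P": P, "I": I, "F": F}[best_symbol]
    return LatticeAssignment(
        assigned=assigned,
        scores=scores,
        per_q=per_q,
        epsilon=epsilon,
        alpha_side=alpha_side,
        aggregate=aggregate,
        W=W,
        cloud_size=len(cloud),
        notes=notes,
    )
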