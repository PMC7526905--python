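"""Ground-truthed synthetic inputs for every pipeline stage.

Two generators are provided.  ``generate_crystal`` realises the fact that
densest packings of identical ellipsoids are affine images of densest sphere
packings: it places the exact fractional motif of a cubic lattice type in an
arbitrary (possibly triclinic) cell and computes analytically the ellipsoid
the estimator must recover, so every generated crystal carries its own ground
truth.  ``generate_ml_dataset`` builds fingerprint -> radii regression data
from a pool of real small aromatic/aliphatic molecules with targets from a
planted sparse linear map of fingerprint bits plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ellipsoid import EllipsoidShape
from .geometry import CellParameters, CrystalCentroids, cell_matrix, normalization_map
from .reference import LatticeType, fractional_motif, reference_ellipsoid

__all__ = [
    "SyntheticCrystalSpec",
    "generate_crystal",
    "random_crystal_spec",
    "generate_ml_dataset",
    "DEFAULT_MOLECULE_POOL",
]

#: small aromatics and aliphatics typical of the organic-semiconductor domain
DEFAULT_MOLECULE_POOL: tuple[str, ...] = (
    "c1ccccc1",                       # benzene
    "c1ccc2ccccc2c1",                 # naphthalene
    "c1ccc2cc3ccccc3cc2c1",           # anthracene
    "c1ccc2c(c1)ccc3ccccc23",         # phenanthrene
    "c1ccc2cc3cc4ccccc4cc3cc2c1",     # naphthacene
    "c1cc2ccc3cccc4ccc(c1)c2c34",     # pyrene
    "c1cnccn1",                       # pyrazine
    "c1ccncc1",                       # pyridine
    "c1ccc2ncccc2c1",                 # quinoline
    "c1ccc2[nH]ccc2c1",               # indole
    "c1ccc2c(c1)oc1ccccc12",          # dibenzofuran
    "c1ccc2c(c1)sc1ccccc12",          # dibenzothiophene
    "c1ccc(-c2ccccc2)cc1",            # biphenyl
    "Cc1ccccc1",                      # toluene
    "Cc1ccc(C)cc1",                   # p-xylene
    "c1ccc(Cl)cc1",                   # chlorobenzene
    "c1ccc(F)cc1",                    # fluorobenzene
    "C1CCCCC1",                       # cyclohexane
    "CCCCCC",                         # hexane
    "CC(C)CC",                        # isopentane
    "c1ccc(/C=C/c2ccccc2)cc1",        # stilbene
    "c1csc(-c2cccs2)c1",              # bithiophene
    "O=c1[nH]c2ccccc2o1",             # benzoxazolone
    "c1cc2cccc3c4cccc5cccc(c(c1)c23)c45",  # perylene
)


@dataclass
class SyntheticCrystalSpec:
    """Recipe for one affine-transformed lattice crystal.

    Either explicit cell parameters or a seed to draw them; ``eta`` is the
    fractional jitter magnitude applied to each centroid coordinate
    (uniform in [-eta, eta]).
    """

    lattice: LatticeType | str
    cell: CellParameters | None = None
    eta: float = 0.0
    seed: int | None = None
    max_condition_number: float = 10.0
    smiles: str | None = None

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("jitter magnitude eta must be >= 0")


#: ranges representative of small-molecule organic cells
_LENGTH_RANGE = (0.3, 1.2)  # nm
_ANGLE_RANGE = (70.0, 110.0)  # degrees


def random_crystal_spec(
    lattice: LatticeType | str,
    rng: np.random.Generator,
    eta: float = 0.0,
    max_condition_number: float = 10.0,
) -> SyntheticCrystalSpec:
    """Draw a random valid cell for ``lattice``, rejecting ill-conditioned ones."""
    for _ in range(1000):
        cell = CellParameters(
            a=rng.uniform(*_LENGTH_RANGE),
            b=rng.uniform(*_LENGTH_RANGE),
            c=rng.uniform(*_LENGTH_RANGE),
            alpha=rng.uniform(*_ANGLE_RANGE),
            beta=rng.uniform(*_ANGLE_RANGE),
            gamma=rng.uniform(*_ANGLE_RANGE),
        )
        try:
            cond = np.linalg.cond(cell_matrix(cell))
        except ValueError:
            continue
        if cond <= max_condition_number:
            return SyntheticCrystalSpec(
                lattice=lattice,
                cell=cell,
                eta=eta,
                seed=int(rng.integers(2**31)),
                max_condition_number=max_condition_number,
            )
    raise RuntimeError("could not draw a well-conditioned cell in 1000 tries")


def generate_crystal(
    spec: SyntheticCrystalSpec,
) -> tuple[CrystalCentroids, EllipsoidShape]:
    """Build the crystal and its planted ground-truth ellipsoid.

    The fractional motif of the lattice type is placed in the cell and
    jittered by ``eta``.  The planted shape is the analytic pull-back of the
    reference ellipsoid through the cell's normalization map — what a correct
    estimator must return at ``eta = 0``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.cell is None:
        spec = random_crystal_spec(spec.lattice, rng, spec.eta, spec.max_condition_number)
        rng = np.random.default_rng(spec.seed)
    A = cell_matrix(spec.cell)
    cond = np.linalg.cond(A)
    if cond > spec.max_condition_number:
        raise ValueError(
            f"cell condition number {cond:.2f} exceeds bound {spec.max_condition_number}"
        )
    frac = fractional_motif(spec.lattice).copy()
    if spec.eta > 0:
        frac = frac + rng.uniform(-spec.eta, spec.eta, size=frac.shape)
    crystal = CrystalCentroids(
        cell=spec.cell, fractional=frac, smiles=spec.smiles, label=f"synthetic-{spec.lattice}"
    )
    # ground truth: pull the reference form back through W analytically
    alpha_side = 0.1
    W = normalization_map(spec.cell, alpha_side).matrix
    R = reference_ellipsoid(spec.lattice, alpha_side).matrix
    Q = W.T @ R @ W
    lam, vec = np.linalg.eigh(0.5 * (Q + Q.T))
    planted = EllipsoidShape(radii=1.0 / np.sqrt(lam), axes=vec, Q=Q)
    return crystal, planted


# ---------------------------------------------------------------------------
# fingerprint -> radii datasets
# ---------------------------------------------------------------------------


@dataclass
class FingerprintDataset:
    """Paired fingerprints and target radii triples (r1 >= r2 >= r3, nm)."""

    X: np.ndarray  # (n, n_bits) binary
    y: np.ndarray  # (n, 3) positive, sorted descending per row
    smiles: list[str]
    n_bits: int
    radius: int
    planted: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0] or self.y.shape[1] != 3:
            raise ValueError("X and y must have matching rows, y three columns")
        if np.any(self.y <= 0) or np.any(np.diff(self.y, axis=1) > 1e-12):
            raise ValueError("targets must be positive and sorted descending")

    def __len__(self) -> int:
        return self.X.shape[0]


def generate_ml_dataset(
    n: int,
    noise_sigma: float = 0.02,
    seed: int | None = None,
    n_bits: int = 2048,
    radius: int = 2,
    pool: tuple[str, ...] | None = None,
    n_weights: int = 64,
    weight_scale: float = 0.05,
    base_radii: tuple[float, float, float] = (0.55, 0.40, 0.28),
) -> FingerprintDataset:
    """Planted-map regression dataset over a pool of real molecules.

    Each record draws a molecule, computes its circular fingerprint, and sets
    the target triple to ``base + W_sel . bits + noise`` for a seeded sparse
    linear map (``n_weights`` active bits per output, weights
    ``N(0, weight_scale^2)``), clipped away from zero and sorted descending.
    The planted parameters are kept for recovery scoring.
    """
    from .fingerprints import compute_fingerprint

    if n < 1:
        raise ValueError("dataset size n must be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    pool = tuple(pool) if pool is not None else DEFAULT_MOLECULE_POOL
    if not pool:
        raise ValueError("molecule pool is empty")
    rng = np.random.default_rng(seed)
    fps = {s: compute_fingerprint(s, radius=radius, n_bits=n_bits).bits for s in pool}
    # only substructures realised in the pool can carry signal; draw the
    # active bits of the planted map from those
    on_union = np.flatnonzero(np.any(np.stack(list(fps.values())), axis=0))
    source = on_union if on_union.size >= 3 * n_weights else np.arange(n_bits)
    sel = rng.choice(source, size=(3, n_weights), replace=source.size < 3 * n_weights)
    weights = rng.normal(0.0, weight_scale, size=(3, n_weights))
    choices = rng.integers(len(pool), size=n)
    smiles = [pool[i] for i in choices]
    X = np.stack([fps[s] for s in smiles]).astype(np.uint8)
    clean = np.stack(
        [base_radii[i] + X[:, sel[i]] @ weights[i] for i in range(3)], axis=1
    )
    y = clean + rng.normal(0.0, noise_sigma, size=clean.shape)
    y = np.clip(y, 0.02, None)
    y = -np.sort(-y, axis=1)
    return FingerprintDataset(
        X=X,
        y=y,
        smiles=smiles,
        n_bits=n_bits,
        radius=radius,
        planted={
            "selected_bits": sel,
            "weights": weights,
            "base_radii": np.asarray(base_radii),
            "noise_sigma": noise_sigma,
            "seed": seed,
        },
    )
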