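"""Reading and writing the pipeline's file formats.

Canonical crystal input is CSV or JSON with fields ``a_nm, b_nm, c_nm,
alpha_deg, beta_deg, gamma_deg, centroids, smiles (optional), id (optional)``.
In JSON, ``centroids`` is a list of ``[fx, fy, fz]`` fractional triples; in
CSV it is a string of whitespace-separated triples joined by ``;``.
Persistence diagrams serialise to CSV rows ``(q, birth_nm, death_nm)`` with
``inf`` allowed.  Optional CIF ingestion delegates cell and atom-site parsing
to gemmi; molecule partitioning must be supplied explicitly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CellParameters, CrystalCentroids
from .persistence import DiagramSet, PersistenceDiagram

__all__ = [
    "read_crystals",
    "write_crystals",
    "diagrams_to_csv",
    "diagrams_from_csv",
    "crystal_from_cif",
]

_CELL_FIELDS = ("a_nm", "b_nm", "c_nm", "alpha_deg", "beta_deg", "gamma_deg")


def _encode_centroids(frac: np.ndarray) -> str:
    return ";".join(" ".join(f"{x:.12g}" for x in row) for row in frac)


def _decode_centroids(text: str) -> np.ndarray:
    rows = [[float(x) for x in part.split()] for part in str(text).split(";") if part.strip()]
    return np.asarray(rows, dtype=float)


def _record_to_crystal(rec: dict) -> tuple[str | None, CrystalCentroids]:
    cell = CellParameters(
        a=float(rec["a_nm"]), b=float(rec["b_nm"]), c=float(rec["c_nm"]),
        alpha=float(rec["alpha_deg"]), beta=float(rec["beta_deg"]), gamma=float(rec["gamma_deg"]),
    )
    cents = rec["centroids"]
    frac = _decode_centroids(cents) if isinstance(cents, str) else np.asarray(cents, float)
    smiles = rec.get("smiles")
    if smiles is not None and (smiles != smiles or smiles == ""):  # NaN / empty
        smiles = None
    ident = rec.get("id")
    return (None if ident is None else str(ident)), CrystalCentroids(
        cell=cell, fractional=frac, smiles=smiles
    )


def read_crystals(path: str | Path) -> list[tuple[str, CrystalCentroids]]:
    """Load (id, crystal) pairs from a canonical CSV or JSON file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if isinstance(records, dict):
            records = records.get("crystals", [records])
    else:
        records = pd.read_csv(path).to_dict(orient="records")
    out = []
    for k, rec in enumerate(records):
        ident, crystal = _record_to_crystal(rec)
        out.append((ident if ident is not None else str(k), crystal))
    return out


def write_crystals(
    path: str | Path, crystals: list[tuple[str, CrystalCentroids]]
) -> None:
    """Write (id, crystal) pairs in the canonical format chosen by extension."""
    path = Path(path)
    records = []
    for ident, c in crystals:
        rec = {
            "id": ident,
            "a_nm": c.cell.a, "b_nm": c.cell.b, "c_nm": c.cell.c,
            "alpha_deg": c.cell.alpha, "beta_deg": c.cell.beta, "gamma_deg": c.cell.gamma,
        }
        if path.suffix.lower() == ".json":
            rec["centroids"] = c.fractional.tolist()
        else:
            rec["centroids"] = _encode_centroids(c.fractional)
        if c.smiles:
            rec["smiles"] = c.smiles
        records.append(rec)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"crystals": records}, indent=1))
    else:
        pd.DataFrame(records).to_csv(path, index=False)


def diagrams_to_csv(path: str | Path, diagrams: DiagramSet) -> None:
    """One row per (birth, death) pair, columns q, birth_nm, death_nm."""
    rows = []
    for q in range(3):
        for b, d in diagrams[q].pairs:
            rows.append({"q": q, "birth_nm": b, "death_nm": d})
    pd.DataFrame(rows, columns=["q", "birth_nm", "death_nm"]).to_csv(path, index=False)


def diagrams_from_csv(path: str | Path) -> DiagramSet:
    df = pd.read_csv(path)
    parts = {}
    for q in range(3):
        sub = df[df["q"] == q]
        parts[q] = PersistenceDiagram(q, sub[["birth_nm", "death_nm"]].to_numpy(float))
    return DiagramSet(d0=parts[0], d1=parts[1], d2=parts[2])


def crystal_from_cif(
    path: str | Path,
    molecule_of: dict[str, int] | list[int],
    mass_weighted: bool = False,
    smiles: str | None = None,
) -> CrystalCentroids:
    """Build centroids from an atomic CIF file (cell lengths converted Å→nm).

    ``molecule_of`` assigns every atom site to a molecule, either by site
    label or positionally; automatic bond perception is deliberately not
    attempted.  Centroids are unweighted means of the atomic Cartesian
    positions by default, optionally mass weighted.
    """
    import gemmi

    st = gemmi.read_small_structure(str(path))
    cell = st.cell
    params = CellParameters(
        a=cell.a / 10.0, b=cell.b / 10.0, c=cell.c / 10.0,
        alpha=cell.alpha, beta=cell.beta, gamma=cell.gamma,
    )
    atoms = [
        (site.label, site.element.weight, np.array([site.fract.x, site.fract.y, site.fract.z]))
        for site in st.sites
    ]
    if isinstance(molecule_of, dict):
        groups = [molecule_of[name] for name, _, _ in atoms]
    else:
        if len(molecule_of) != len(atoms):
            raise ValueError(f"molecule map has {len(molecule_of)} entries for {len(atoms)} atoms")
        groups = list(molecule_of)
    frac_centroids = []
    for g in sorted(set(groups)):
        members = [i for i, gi in enumerate(groups) if gi == g]
        coords = np.stack([atoms[i][2] for i in members])
        if mass_weighted:
            w = np.array([atoms[i][1] for i in members])
            frac_centroids.append((coords * w[:, None]).sum(0) / w.sum())
        else:
            frac_centroids.append(coords.mean(0))
    return CrystalCentroids(cell=params, fractional=np.asarray(frac_centroids), smiles=smiles)
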