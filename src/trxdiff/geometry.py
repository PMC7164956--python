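"""Structural metrics: torsion angles, Kabsch superposition, radial displacement.

These are the quantities used to describe a photoproduct relative to its dark
state: the chromophore ring twist as a four-atom torsion, whole-model RMSD
after optimal rigid superposition, and the mean change in distance of a
residue stretch from a reference atom (e.g. a helix moving away from the
pyrrole water at the chromophore center).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import AtomicModel

__all__ = ["DihedralSpec", "dihedral", "dihedral_from_spec", "kabsch_rmsd", "mean_displacement"]


class GeometryError(ValueError):
    """Raised for degenerate or mismatched geometry inputs."""


@dataclass(frozen=True)
class DihedralSpec:
    """Four atom identifiers (chain, residue number, atom name) defining a torsion."""

    atoms: tuple[tuple[str, int, str], tuple[str, int, str], tuple[str, int, str], tuple[str, int, str]]

    def __post_init__(self) -> None:
        if len(set(self.atoms)) != 4:
            raise GeometryError("dihedral requires four distinct atoms")

    def resolve(self, model: AtomicModel) -> np.ndarray:
        return np.array([model.find_atom(*ident).xyz for ident in self.atoms])


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention, (-180, 180].

    Positive means clockwise rotation of p4 relative to p1 when viewed from
    p2 toward p3.  Invariant under rigid rotation and translation.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-10:
        raise GeometryError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear points: torsion undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    angle = np.degrees(np.arctan2(y, x))
    if angle <= -180.0:
        angle += 360.0
    return float(angle)


def dihedral_from_spec(model: AtomicModel, spec: DihedralSpec) -> float:
    """Torsion angle for four named atoms of a model."""
    return dihedral(*spec.resolve(model))


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares optimal superposition of matched coordinate sets.

    Returns (rmsd, rotation, translation) such that
    ``coords_a @ rotation.T + translation`` best matches ``coords_b`` with a
    proper rotation (determinant +1).  Correspondence is positional; at least
    three point pairs are required.
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise GeometryError(f"coordinate count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 3:
        raise GeometryError("need at least 3 point pairs for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cb - rot @ ca
    moved = a @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return rmsd, rot, trans


def mean_displacement(
    model_a: AtomicModel,
    model_b: AtomicModel,
    selection: AtomicModel,
    reference: tuple[str, int, str],
) -> tuple[float, pd.DataFrame]:
    """Mean change in distance of selected atoms from a reference atom.

    For each atom in ``selection`` (resolved by chain/residue/name in both
    models), the signed displacement is
    dist(position_in_b, ref) - dist(position_in_a, ref), with the reference
    atom taken from ``model_a``.  Positive values mean the atom moved away
    from the reference.  Returns the mean and a per-atom table.
    """
    ref = model_a.find_atom(*reference).xyz
    rows = []
    missing = []
    for atom in selection.atoms:
        ident = (atom.chain_id, atom.residue_number, atom.name)
        try:
            pa = model_a.find_atom(*ident).xyz
            pb = model_b.find_atom(*ident).xyz
        except Exception:
            missing.append("/".join(map(str, ident)))
            continue
        da = float(np.linalg.norm(pa - ref))
        db = float(np.linalg.norm(pb - ref))
        rows.append({"atom": "/".join(map(str, ident)), "d_a": da, "d_b": db, "delta": db - da})
    if missing:
        raise GeometryError(f"selection atoms missing from a model: {missing}")
    if not rows:
        raise GeometryError("empty selection")
    table = pd.DataFrame(rows)
    return float(table["delta"].mean()), table
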