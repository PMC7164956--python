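"""Atomic models: a thin, ordered container over PDB-subset coordinate files.

The analysis chain needs exactly four things from a model file: element,
Cartesian position, isotropic B and occupancy, plus the unit cell.  Everything
else in a PDB file (ANISOU, LINK, REMARK, ...) is ignored.  gemmi does the
fixed-column parsing and writing; this module flattens its hierarchy into a
stable, ordered list of :class:`Atom` so that downstream stages (structure
factors, geometry, peak attribution) can index atoms positionally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: elements with embedded scattering coefficients (see sf_calc)
KNOWN_ELEMENTS = frozenset({"H", "C", "N", "O", "P", "S", "FE"})


class ModelError(ValueError):
    """Raised for malformed or unsupported model content."""


@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell, lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ModelError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ModelError(f"cell angles must lie in (0, 180): {self}")
        if self.volume <= 0:
            raise ModelError(f"cell volume non-positive: {self}")

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        return self.a * self.b * self.c * math.sqrt(max(arg, 0.0))

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix taking fractional to Cartesian coordinates (PDB convention)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume / (self.a * self.b * self.c)
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def fractionalization_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orthogonalization_matrix)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d(hkl) in Angstrom for an (N, 3) integer index array."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        # reciprocal metric tensor from the fractionalization matrix
        f = self.fractionalization_matrix
        g_star = f @ f.T
        inv_d2 = np.einsum("ni,ij,nj->n", hkl, g_star, hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class Atom:
    """One atom: element, identifiers, Cartesian position (A), B (A^2), occupancy."""

    element: str
    name: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: tuple[float, float, float]
    b_factor: float = 20.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ModelError(f"occupancy outside [0, 1] for atom {self.name}: {self.occupancy}")
        if self.b_factor < 0:
            raise ModelError(f"negative B factor for atom {self.name}: {self.b_factor}")
        if self.element.upper() not in KNOWN_ELEMENTS:
            raise ModelError(
                f"element {self.element!r} of atom {self.name} has no tabulated "
                f"scattering coefficients (known: {sorted(KNOWN_ELEMENTS)})"
            )

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    def moved_to(self, position: np.ndarray) -> "Atom":
        return replace(self, position=tuple(float(v) for v in position))


@dataclass
class AtomicModel:
    """Ordered atoms in a unit cell; order is stable under read -> write -> read."""

    atoms: list[Atom]
    cell: UnitCell
    space_group: str = "P 1"

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        """(N, 3) Cartesian coordinates in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def fractional_positions(self) -> np.ndarray:
        return self.positions() @ self.cell.fractionalization_matrix.T

    def atom_labels(self) -> list[str]:
        """Human-readable identifiers, e.g. ``A/HOH 5/O``."""
        return [f"{a.chain_id}/{a.residue_name} {a.residue_number}/{a.name}" for a in self.atoms]

    def find_atom(self, chain_id: str, residue_number: int, name: str) -> Atom:
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_number == residue_number and a.name == name:
                return a
        raise ModelError(f"atom {chain_id}/{residue_number}/{name} not found")

    def with_positions(self, positions: np.ndarray) -> "AtomicModel":
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.atoms), 3):
            raise ModelError("position array shape does not match atom count")
        return AtomicModel(
            atoms=[a.moved_to(p) for a, p in zip(self.atoms, positions)],
            cell=self.cell,
            space_group=self.space_group,
        )


def read_model(text: str, cell: UnitCell | None = None) -> AtomicModel:
    """Parse PDB-format text into an :class:`AtomicModel`.

    Only ATOM/HETATM and CRYST1 records are consumed; all other record types
    are ignored (counted in a debug log line).  Alternate locations other than
    blank or 'A' are dropped with a warning.  The element is taken from
    columns 77-78 when present, otherwise inferred from the atom name.

    Parameters
    ----------
    text : PDB-format content with at least one ATOM/HETATM record.
    cell : fallback unit cell if the text has no CRYST1 record.
    """
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ModelError(f"PDB parse error: {exc}") from exc

    n_other = sum(
        1
        for line in text.splitlines()
        if line.strip() and not line.startswith(("ATOM", "HETATM", "CRYST1", "END", "TER"))
    )
    if n_other:
        logger.debug("ignored %d non-coordinate records", n_other)

    if structure.cell.is_crystal():
        g = structure.cell
        model_cell = UnitCell(g.a, g.b, g.c, g.alpha, g.beta, g.gamma)
    elif cell is not None:
        model_cell = cell
    else:
        raise ModelError("no CRYST1 record and no fallback cell supplied")

    space_group = structure.spacegroup_hm or "P 1"

    atoms: list[Atom] = []
    n_dropped_alt = 0
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.altloc not in ("", "\0", "A"):
                        n_dropped_alt += 1
                        continue
                    element = atom.element.name.upper()
                    if element in ("", "X"):
                        raise ModelError(f"cannot determine element for atom {atom.name!r}")
                    atoms.append(
                        Atom(
                            element=element,
                            name=atom.name,
                            residue_name=residue.name,
                            residue_number=residue.seqid.num,
                            chain_id=chain.name,
                            position=(atom.pos.x, atom.pos.y, atom.pos.z),
                            b_factor=atom.b_iso,
                            occupancy=atom.occ,
                        )
                    )
        break  # first MODEL only
    if n_dropped_alt:
        logger.warning("dropped %d alternate-location atoms (kept altloc '' or 'A')", n_dropped_alt)
    if not atoms:
        raise ModelError("no ATOM/HETATM records found")
    return AtomicModel(atoms=atoms, cell=model_cell, space_group=space_group)


def write_model(model: AtomicModel) -> str:
    """Serialize a model to standard 80-column PDB text (CRYST1 + ATOM/HETATM)."""
    structure = gemmi.Structure()
    structure.cell = model.cell.to_gemmi()
    structure.spacegroup_hm = model.space_group
    gmodel = gemmi.Model("1")

    chains: dict[str, gemmi.Chain] = {}
    for atom in model.atoms:
        chain = chains.get(atom.chain_id)
        if chain is None:
            chain = gemmi.Chain(atom.chain_id)
            chains[atom.chain_id] = chain
            gmodel.add_chain(chain)
            chain = gmodel[-1]
            chains[atom.chain_id] = chain
        if len(chain) == 0 or chain[-1].seqid.num != atom.residue_number or chain[-1].name != atom.residue_name:
            residue = gemmi.Residue()
            residue.name = atom.residue_name
            residue.seqid = gemmi.SeqId(atom.residue_number, " ")
            residue.het_flag = "H" if atom.residue_name in ("HOH", "WAT") else "A"
            chain.add_residue(residue)
        residue = chain[-1]
        ga = gemmi.Atom()
        ga.name = atom.name
        ga.element = gemmi.Element(atom.element.capitalize())
        ga.pos = gemmi.Position(*atom.position)
        ga.b_iso = atom.b_factor
        ga.occ = atom.occupancy
        residue.add_atom(ga)

    structure.add_model(gmodel)
    structure.setup_entities()
    return structure.make_pdb_string()


def select(
    model: AtomicModel,
    chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
    atom_names: set[str] | None = None,
) -> AtomicModel:
    """Subset a model by chain id, inclusive residue-number range and atom names.

    Criteria are ANDed; ``None`` means "any".  Atom order is preserved and an
    empty selection is valid.
    """
    if residue_range is not None:
        lo, hi = residue_range
        if lo > hi:
            raise ModelError(f"residue range lower bound {lo} exceeds upper bound {hi}")

    def keep(a: Atom) -> bool:
        if chain is not None and a.chain_id != chain:
            return False
        if residue_range is not None and not residue_range[0] <= a.residue_number <= residue_range[1]:
            return False
        if atom_names is not None and a.name not in atom_names:
            return False
        return True

    return AtomicModel(
        atoms=[a for a in model.atoms if keep(a)],
        cell=model.cell,
        space_group=model.space_group,
    )
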