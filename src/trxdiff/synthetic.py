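"""Toy crystals with known ground truth for exercising the analysis chain.

The generator emulates the statistical structure of a time-resolved
pump-probe crystallography experiment at desk scale: a small P1 cell holding
a chromophore-like planar four-atom "ring arm" whose terminal nitrogen can
twist about a bond (the analogue of a bilin D-ring twist), an anchor triad,
a "pyrrole-water-like" oxygen hydrogen-bond distance from the arm, and a
stationary scaffold of heavier scatterers.  The scaffold matters: in a real
protein crystal the atoms that move at 1 ps are a tiny fraction of the total
scattering mass, which is what makes borrowing dark-model phases a good
approximation.  The toy reproduces that regime by keeping the perturbed
group (the arm nitrogen and the water, ~15 electrons) small against the
stationary scattering (~230 electrons).

The photoproduct is derived from the dark state by a known dihedral twist
plus a water displacement.  Observed amplitude sets mix the two states
coherently at a known population,

    F_obs_light = | (1-p) Fc_dark + p Fc_light | * (1 + eps),

so the difference-Fourier treatment downstream is — as in a real crystal —
an approximation to the ground truth, and multiplicative Gaussian amplitude
noise exercises the q-weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import dihedral
from .model_io import Atom, AtomicModel, UnitCell
from .sf_calc import ReflectionSet, calc_structure_factors, generate_hkl

__all__ = [
    "SyntheticTruth",
    "make_toy_dark",
    "perturb_light",
    "simulate_observations",
    "make_fixture",
    "ARM_DIHEDRAL_ATOMS",
    "ROTATING_ATOM_NAMES",
    "WATER_IDENT",
]

TOY_CELL = UnitCell(22.0, 22.0, 22.0, 90.0, 90.0, 90.0)

#: atom names (chain A, residue 1 CHR) defining the arm torsion, in order
ARM_DIHEDRAL_ATOMS = (("A", 1, "C14"), ("A", 1, "C15"), ("A", 1, "C16"), ("A", 1, "ND"))
#: atoms distal to the C15-C16 bond: these rotate under the twist
ROTATING_ATOM_NAMES = ("ND",)
WATER_IDENT = ("A", 5, "O")

# base Cartesian coordinates (A).  The planar trans arm lies in the z=11
# plane; the water oxygen sits 2.87 A from ND, displaced out of the arm
# plane, with a low B (a well-ordered structural water, so that its complete
# displacement produces the deepest difference feature, as for a
# photodissociating pyrrole water).  The scaffold Fe/S/O/N/C atoms are
# spread through the cell and never move.
_BASE_ATOMS: list[tuple[str, str, str, int, tuple[float, float, float], float]] = [
    # element, name, residue, resnum, position, B
    ("C", "C14", "CHR", 1, (7.0, 9.3, 11.0), 12.0),
    ("C", "C15", "CHR", 1, (8.4, 9.3, 11.0), 12.0),
    ("C", "C16", "CHR", 1, (9.1, 10.5, 11.0), 12.0),
    ("N", "ND", "CHR", 1, (10.5, 10.5, 11.0), 12.0),
    ("N", "N", "ANC", 2, (14.5, 15.0, 15.0), 14.0),
    ("C", "CA", "ANC", 2, (15.9, 15.0, 15.0), 14.0),
    ("O", "O", "ANC", 2, (16.6, 16.2, 15.0), 14.0),
    ("O", "O", "HOH", 5, (10.5, 8.5, 13.0), 8.0),
    ("FE", "FE1", "SCF", 6, (4.0, 5.0, 16.0), 12.0),
    ("FE", "FE2", "SCF", 6, (17.0, 17.5, 6.0), 12.0),
    ("FE", "FE3", "SCF", 7, (6.5, 13.0, 4.5), 12.0),
    ("FE", "FE4", "SCF", 7, (13.0, 4.0, 8.0), 12.0),
    ("S", "SG1", "SCF", 8, (18.4, 16.8, 6.5), 13.0),
    ("S", "SG2", "SCF", 8, (5.3, 5.6, 16.2), 13.0),
    ("S", "SG3", "SCF", 9, (6.0, 4.5, 15.8), 13.0),
    ("S", "SG4", "SCF", 9, (7.6, 13.8, 4.2), 13.0),
    ("O", "O1", "SCF", 10, (11.0, 17.0, 17.5), 13.0),
    ("O", "O2", "SCF", 10, (3.5, 11.0, 10.0), 13.0),
    ("N", "N1", "SCF", 11, (16.5, 10.5, 3.5), 13.0),
    ("C", "C1", "SCF", 11, (10.0, 3.0, 17.0), 13.0),
]


def make_toy_dark(seed: int = 1) -> AtomicModel:
    """Deterministic toy dark-state model in a 22 A cubic P1 cell.

    Twenty non-hydrogen atoms: the four-atom planar ring arm C14-C15-C16-ND,
    a three-atom anchor triad, one water oxygen ~2.9 A from ND, and a
    twelve-atom stationary scaffold.  Different seeds jitter all coordinates
    by at most 0.05 A per axis without changing the topology.
    """
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(-0.05, 0.05, size=(len(_BASE_ATOMS), 3))
    atoms = [
        Atom(
            element=el,
            name=name,
            residue_name=res,
            residue_number=num,
            chain_id="A",
            position=tuple(np.asarray(pos) + j),
            b_factor=b,
            occupancy=1.0,
        )
        for (el, name, res, num, pos, b), j in zip(_BASE_ATOMS, jitter)
    ]
    return AtomicModel(atoms=atoms, cell=TOY_CELL, space_group="P 1")


def _rotate_about_axis(points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of points about the line (origin, axis)."""
    u = axis / np.linalg.norm(axis)
    theta = np.radians(angle_deg)
    p = points - origin
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rotated = p * cos_t + np.cross(u, p) * sin_t + np.outer(p @ u, u) * (1 - cos_t)
    return rotated + origin


def _arm_dihedral(model: AtomicModel) -> float:
    return dihedral(*(model.find_atom(*ident).xyz for ident in ARM_DIHEDRAL_ATOMS))


def perturb_light(
    dark: AtomicModel,
    twist_deg: float,
    water_shift: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> AtomicModel:
    """Photoproduct model: twist the terminal arm atom, displace the water.

    The atoms distal to the C15-C16 bond are rotated about that bond axis so
    that the measured C14-C15-C16-ND torsion changes by exactly
    ``twist_deg``; the water oxygen is translated by ``water_shift`` (A).
    All other atoms are untouched.
    """
    c15 = dark.find_atom("A", 1, "C15").xyz
    c16 = dark.find_atom("A", 1, "C16").xyz
    axis = c16 - c15
    if np.linalg.norm(axis) < 1e-8:
        raise ValueError("degenerate twist axis: C15 and C16 coincide")

    positions = dark.positions().copy()
    rot_idx = [i for i, a in enumerate(dark.atoms) if a.residue_number == 1 and a.name in ROTATING_ATOM_NAMES]
    water_idx = [
        i
        for i, a in enumerate(dark.atoms)
        if (a.chain_id, a.residue_number, a.name) == WATER_IDENT
    ]

    def build(angle: float) -> AtomicModel:
        pos = positions.copy()
        pos[rot_idx] = _rotate_about_axis(positions[rot_idx], c16, axis, angle)
        for i in water_idx:
            pos[i] = positions[i] + np.asarray(water_shift, dtype=float)
        return dark.with_positions(pos)

    light = build(twist_deg)
    if twist_deg != 0.0:
        # fix the rotation sense so the measured torsion change is +twist_deg
        change = (_arm_dihedral(light) - _arm_dihedral(dark) + 180.0) % 360.0 - 180.0
        if abs(change - twist_deg) > 1e-6:
            light = build(-twist_deg)
    return light


def simulate_observations(
    dark: AtomicModel,
    light: AtomicModel,
    population: float,
    noise_rel: float,
    d_min: float,
    seed: int,
) -> tuple[ReflectionSet, ReflectionSet]:
    """Observed amplitude sets for the dark and the partially activated crystal.

    Fo_dark = |Fc_dark| (1 + eps);
    Fo_light = |(1-p) Fc_dark + p Fc_light| (1 + eps'), complex two-state
    mixing, with eps, eps' i.i.d. N(0, noise_rel^2) and sigma columns set to
    noise_rel * amplitude.
    """
    if not 0.0 <= population <= 1.0:
        raise ValueError(f"population must be in [0, 1], got {population}")
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hkl = generate_hkl(dark.cell, d_min)
    fc_dark = calc_structure_factors(dark, hkl, label="Fc_dark")
    fc_light = calc_structure_factors(light, hkl, label="Fc_light")
    mixed = (1.0 - population) * fc_dark.complex_values() + population * fc_light.complex_values()

    rng = np.random.default_rng(seed)
    eps_dark = rng.normal(0.0, noise_rel, size=len(hkl)) if noise_rel > 0 else 0.0
    eps_light = rng.normal(0.0, noise_rel, size=len(hkl)) if noise_rel > 0 else 0.0
    amp_dark = np.abs(fc_dark.amplitude * (1.0 + eps_dark))
    amp_light = np.abs(np.abs(mixed) * (1.0 + eps_light))

    fo_dark = ReflectionSet(
        hkl=hkl, amplitude=amp_dark, cell=dark.cell, sigma=noise_rel * amp_dark, label="Fo_dark"
    )
    fo_light = ReflectionSet(
        hkl=hkl, amplitude=amp_light, cell=dark.cell, sigma=noise_rel * amp_light, label="Fo_light"
    )
    return fo_dark, fo_light


@dataclass
class SyntheticTruth:
    """A complete synthetic experiment with its ground truth.

    Holds the dark and photoproduct models, the mixing population, the
    applied twist and noise level, the seed, the pure calculated sets and the
    noisy observed sets — everything the recovery tests compare against.
    """

    dark_model: AtomicModel
    light_model: AtomicModel
    population: float
    twist_deg: float
    water_shift: tuple[float, float, float]
    noise_rel: float
    d_min: float
    seed: int
    fc_dark: ReflectionSet
    fc_light: ReflectionSet
    fo_dark: ReflectionSet
    fo_light: ReflectionSet

    def perturbed_atom_indices(self) -> list[int]:
        """Indices of the atoms that differ between dark and light models."""
        moved = np.linalg.norm(self.dark_model.positions() - self.light_model.positions(), axis=1)
        return [int(i) for i in np.where(moved > 1e-9)[0]]


def make_fixture(
    population: float = 0.08,
    twist_deg: float = 70.0,
    water_shift: tuple[float, float, float] = (1.5, 0.0, 0.0),
    noise_rel: float = 0.0,
    d_min: float = 1.5,
    seed: int = 1,
) -> SyntheticTruth:
    """One call building the standard reference fixture.

    Defaults are the reference conditions for the recovery tests: 8%
    photoactivated population, a 70 degree arm twist, a 1.5 A water
    displacement, 1.5 A resolution, noiseless.
    """
    dark = make_toy_dark(seed)
    light = perturb_light(dark, twist_deg, water_shift)
    fo_dark, fo_light = simulate_observations(dark, light, population, noise_rel, d_min, seed)
    hkl = fo_dark.hkl
    return SyntheticTruth(
        dark_model=dark,
        light_model=light,
        population=population,
        twist_deg=twist_deg,
        water_shift=tuple(water_shift),
        noise_rel=noise_rel,
        d_min=d_min,
        seed=seed,
        fc_dark=calc_structure_factors(dark, hkl, label="Fc_dark"),
        fc_light=calc_structure_factors(light, hkl, label="Fc_light"),
        fo_dark=fo_dark,
        fo_light=fo_light,
    )
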