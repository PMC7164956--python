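"""Structure factors by direct summation with Gaussian atomic form factors.

This is the reciprocal-space engine of the pipeline: it produces calculated
dark amplitudes/phases (Fc_dark) and, in the synthetic-data module, every
"observed" amplitude set.  Direct summation over atoms,

    F(h) = sum_j occ_j * f_j(s) * exp(-B_j s^2) * exp(2 pi i h . x_j),

with s = sin(theta)/lambda = 1/(2 d), is exact at toy-crystal scale and
therefore doubles as the oracle against which the FFT-based map synthesis is
verified.  Form factors use the standard four-Gaussian-plus-constant
(Cromer-Mann) parametrization with coefficients embedded for the elements the
pipeline encounters (H, C, N, O, P, S, Fe).

The Debye-Waller convention used throughout is exp(-B s^2) with s in 1/A,
equivalently exp(-B / (4 d^2)).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
import pandas as pd

from .model_io import AtomicModel, UnitCell

__all__ = [
    "Reflection",
    "ReflectionSet",
    "generate_hkl",
    "form_factor",
    "calc_structure_factors",
    "read_reflections",
    "write_reflections",
]

# Cromer-Mann coefficients (a1..a4, b1..b4, c), International Tables style.
CROMER_MANN: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879), (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000), (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630), (0.005700, 9.89330, 28.9975, 0.582600), -11.529),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000), (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080), (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630), (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
    "FE": ((11.7695, 7.35730, 3.52220, 2.30450), (4.76110, 0.307200, 15.3535, 76.8805), 1.03690),
}

SUPPORTED_SPACE_GROUPS = ("P 1", "P 21 21 21")


class ReflectionError(ValueError):
    """Raised for malformed reflection data or unsupported requests."""


@dataclass(frozen=True)
class Reflection:
    """A single indexed reflection; convenience view, the bulk container is array-based."""

    h: int
    k: int
    l: int
    amplitude: float
    sigma: float | None = None
    phase: float | None = None
    weight: float | None = None


@dataclass
class ReflectionSet:
    """Miller-indexed amplitudes with optional sigmas, phases and weights.

    ``amplitude`` is signed for difference coefficients (the difference-Fourier
    convention stores w*(|Fo_light| - |Fo_dark|) with its sign); plain
    amplitude sets are non-negative.  Phases are degrees in [-180, 180).
    """

    hkl: np.ndarray  # (N, 3) int
    amplitude: np.ndarray  # (N,) float, signed for difference sets
    cell: UnitCell
    sigma: np.ndarray | None = None
    phase: np.ndarray | None = None  # degrees
    weight: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.amplitude = np.asarray(self.amplitude, dtype=float).reshape(-1)
        if len(self.amplitude) != len(self.hkl):
            raise ReflectionError("amplitude length does not match hkl")
        for name in ("sigma", "phase", "weight"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float).reshape(-1)
                if len(arr) != len(self.hkl):
                    raise ReflectionError(f"{name} length does not match hkl")
                setattr(self, name, arr)
        keys = self.index_keys()
        if len(np.unique(keys)) != len(keys):
            raise ReflectionError("duplicate (h,k,l) indices in reflection set")

    def __len__(self) -> int:
        return len(self.hkl)

    def index_keys(self) -> np.ndarray:
        """Unique scalar key per (h,k,l), used for set intersection."""
        h, k, l = self.hkl.T
        return (h.astype(np.int64) * 2048 + k) * 2048 + l

    def d_spacings(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    def s_values(self) -> np.ndarray:
        """sin(theta)/lambda = 1/(2d) per reflection, in 1/A."""
        return 0.5 / self.d_spacings()

    def complex_values(self) -> np.ndarray:
        """Signed amplitude combined with phase into complex coefficients."""
        if self.phase is None:
            raise ReflectionError(f"reflection set {self.label!r} has no phases")
        return self.amplitude * np.exp(1j * np.radians(self.phase))

    def copy(self, **changes) -> "ReflectionSet":
        defaults = dict(
            hkl=self.hkl.copy(),
            amplitude=self.amplitude.copy(),
            cell=self.cell,
            sigma=None if self.sigma is None else self.sigma.copy(),
            phase=None if self.phase is None else self.phase.copy(),
            weight=None if self.weight is None else self.weight.copy(),
            label=self.label,
        )
        defaults.update(changes)
        return ReflectionSet(**defaults)

    def take(self, indices: np.ndarray, label: str | None = None) -> "ReflectionSet":
        return ReflectionSet(
            hkl=self.hkl[indices],
            amplitude=self.amplitude[indices],
            cell=self.cell,
            sigma=None if self.sigma is None else self.sigma[indices],
            phase=None if self.phase is None else self.phase[indices],
            weight=None if self.weight is None else self.weight[indices],
            label=self.label if label is None else label,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"h": self.hkl[:, 0], "k": self.hkl[:, 1], "l": self.hkl[:, 2], "F": self.amplitude}
        data["sigF"] = self.sigma if self.sigma is not None else np.full(len(self), np.nan)
        data["phi"] = self.phase if self.phase is not None else np.full(len(self), np.nan)
        data["weight"] = self.weight if self.weight is not None else np.full(len(self), np.nan)
        return pd.DataFrame(data)


def common_indices(a: ReflectionSet, b: ReflectionSet) -> tuple[np.ndarray, np.ndarray]:
    """Positions (ia, ib) of the shared (h,k,l) set, in matched order."""
    ka, kb = a.index_keys(), b.index_keys()
    shared, ia, ib = np.intersect1d(ka, kb, return_indices=True)
    return ia, ib


def write_reflections(rset: ReflectionSet) -> str:
    """Tab-separated text: header then ``h k l F sigF phi weight`` rows.

    Absent columns are written as empty fields.
    """
    frame = rset.to_frame()
    buf = io.StringIO()
    frame.to_csv(buf, sep="\t", index=False, float_format="%.8g", na_rep="")
    return buf.getvalue()


def read_reflections(text: str, cell: UnitCell, label: str = "") -> ReflectionSet:
    """Parse the tabular reflection format produced by :func:`write_reflections`."""
    frame = pd.read_csv(io.StringIO(text), sep="\t")
    required = {"h", "k", "l", "F"}
    if not required.issubset(frame.columns):
        raise ReflectionError(f"reflection table missing columns {sorted(required - set(frame.columns))}")

    def col(name: str) -> np.ndarray | None:
        if name not in frame.columns or frame[name].isna().all():
            return None
        return frame[name].to_numpy(dtype=float)

    return ReflectionSet(
        hkl=frame[["h", "k", "l"]].to_numpy(dtype=int),
        amplitude=frame["F"].to_numpy(dtype=float),
        cell=cell,
        sigma=col("sigF"),
        phase=col("phi"),
        weight=col("weight"),
        label=label,
    )


def generate_hkl(cell: UnitCell, d_min: float, d_max: float = 1e6) -> np.ndarray:
    """Unique-hemisphere Miller indices with d_min <= d <= d_max.

    One representative per Friedel pair: h > 0, or (h = 0, k > 0), or
    (h = k = 0, l > 0).  (0,0,0) is excluded.
    """
    if not 0 < d_min < d_max:
        raise ReflectionError(f"require 0 < d_min < d_max, got d_min={d_min}, d_max={d_max}")
    hmax = int(np.floor(cell.a / d_min)) + 1
    kmax = int(np.floor(cell.b / d_min)) + 1
    lmax = int(np.floor(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(0, hmax + 1), np.arange(-kmax, kmax + 1), np.arange(-lmax, lmax + 1), indexing="ij"
    )
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    hemi = (hkl[:, 0] > 0) | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0)) | (
        (hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0)
    )
    hkl = hkl[hemi]
    d = cell.d_spacing(hkl)
    keep = (d >= d_min) & (d <= d_max)
    hkl = hkl[keep]
    # deterministic order: by resolution (descending d), then h, k, l
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0], -d[keep]))
    return hkl[order]


def form_factor(element: str, s: float | np.ndarray) -> float | np.ndarray:
    """Atomic scattering factor f(s) in electrons at s = sin(theta)/lambda (1/A).

    Four-Gaussian-plus-constant parametrization; f(0) equals the electron
    count of the neutral atom to tabulation accuracy.
    """
    key = element.upper()
    if key not in CROMER_MANN:
        raise ReflectionError(f"no form-factor coefficients for element {element!r}")
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ReflectionError("s = sin(theta)/lambda must be non-negative")
    a, b, c = CROMER_MANN[key]
    s2 = s * s
    val = c + sum(ai * np.exp(-bi * s2) for ai, bi in zip(a, b))
    return float(val) if val.ndim == 0 else val


def _symmetry_expanded_fractionals(model: AtomicModel) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Fractional coordinates, occupancies, Bs and elements after expanding to P1."""
    sg_name = model.space_group.strip()
    sg = gemmi.find_spacegroup_by_name(sg_name)
    if sg is None or sg.hm not in SUPPORTED_SPACE_GROUPS:
        raise ReflectionError(f"unsupported space group {model.space_group!r}; supported: {SUPPORTED_SPACE_GROUPS}")
    frac = model.fractional_positions()
    occ = np.array([a.occupancy for a in model.atoms])
    b_iso = np.array([a.b_factor for a in model.atoms])
    elements = [a.element.upper() for a in model.atoms]
    if sg.hm == "P 1":
        return frac, occ, b_iso, elements
    all_frac, all_occ, all_b, all_el = [], [], [], []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        all_frac.append(frac @ rot.T + tran)
        all_occ.append(occ)
        all_b.append(b_iso)
        all_el.extend(elements)
    return np.vstack(all_frac), np.concatenate(all_occ), np.concatenate(all_b), all_el


def calc_structure_factors(model: AtomicModel, hkls: np.ndarray, label: str = "Fc") -> ReflectionSet:
    """Complex structure factors of a model by direct summation.

    Returns a :class:`ReflectionSet` carrying amplitudes (electrons) and
    phases (degrees).  P212121 models are expanded to their P1 equivalent
    positions before summation.  Deterministic.
    """
    hkls = np.asarray(hkls, dtype=int).reshape(-1, 3)
    frac, occ, b_iso, elements = _symmetry_expanded_fractionals(model)
    s = 0.5 / model.cell.d_spacing(hkls)  # (R,)
    s2 = s * s

    # per-element form factor table over the reflection list
    f_by_element = {el: form_factor(el, s) for el in set(elements)}
    f_atoms = np.stack([f_by_element[el] for el in elements])  # (A, R)

    damping = np.exp(-np.outer(b_iso, s2))  # (A, R)
    phase_arg = 2.0 * np.pi * (frac @ hkls.T)  # (A, R)
    contrib = (occ[:, None] * f_atoms * damping) * np.exp(1j * phase_arg)
    F = contrib.sum(axis=0)

    amplitude = np.abs(F)
    phase = np.degrees(np.angle(F))
    phase[amplitude < 1e-12] = 0.0
    # wrap to [-180, 180)
    phase = ((phase + 180.0) % 360.0) - 180.0
    return ReflectionSet(hkl=hkls, amplitude=amplitude, cell=model.cell, phase=phase, label=label)
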