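"""Photolysis photon-budget arithmetic for pump-probe crystallography.

Given the pump wavelength, the pulse fluence at the sample and the
chromophore's molar extinction coefficient, this module computes the photon
energy, the photon fluence, the absorption cross-section per molecule and the
resulting mean number of absorbed photons per chromophore, optionally reduced
by a scattering/shading attenuation factor (e.g. light scattering in a
grease carrier jet).  All relations are linear, so the chain is a sequence of
unit conversions:

    E_photon       = h c / lambda                       [J]
    photon fluence = pulse fluence / E_photon           [photons / mm^2]
    sigma          = ln(10) * eps * 1000 / N_A          [cm^2] -> mm^2 (x100)
    photons/molec  = fluence * sigma / attenuation
"""

from __future__ import annotations

from dataclasses import dataclass

# CODATA values
PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m / s
AVOGADRO = 6.02214076e23  # 1 / mol


class BudgetError(ValueError):
    """Raised for unphysical excitation parameters."""


@dataclass(frozen=True)
class ExcitationSpec:
    """Pump-laser and chromophore parameters for the photon-budget chain.

    Attributes
    ----------
    wavelength : pump wavelength in nm (visible/near-IR range).
    pulse_fluence : pulse energy density at the sample, mJ/mm^2.
    epsilon : molar extinction coefficient at the pump wavelength, 1/(M cm).
    attenuation_factor : scalar >= 1 by which the effective fluence at the
        chromophores is reduced (carrier-medium scattering, shading); 1 means
        no attenuation.
    """

    wavelength: float
    pulse_fluence: float
    epsilon: float
    attenuation_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 200.0 < self.wavelength < 1100.0:
            raise BudgetError(f"wavelength {self.wavelength} nm outside (200, 1100)")
        if self.pulse_fluence <= 0:
            raise BudgetError("pulse fluence must be positive")
        if self.epsilon <= 0:
            raise BudgetError("extinction coefficient must be positive")
        if self.attenuation_factor < 1:
            raise BudgetError("attenuation factor must be >= 1")


def photon_energy(wavelength_nm: float) -> float:
    """Photon energy h*c/lambda in joules for a wavelength in nm."""
    if wavelength_nm <= 0:
        raise BudgetError(f"wavelength must be positive, got {wavelength_nm}")
    return PLANCK_H * SPEED_OF_LIGHT / (wavelength_nm * 1e-9)


def photon_fluence(pulse_fluence_mj_mm2: float, wavelength_nm: float) -> float:
    """Photons per mm^2 delivered by a pulse fluence (mJ/mm^2) at a wavelength (nm)."""
    if pulse_fluence_mj_mm2 <= 0:
        raise BudgetError("pulse fluence must be positive")
    return pulse_fluence_mj_mm2 * 1e-3 / photon_energy(wavelength_nm)


def cross_section(epsilon_m_cm: float) -> float:
    """Absorption cross-section per molecule in mm^2 from a molar extinction coefficient.

    sigma = ln(10) * epsilon * 1000 / N_A gives cm^2 per molecule (the 1000
    converts litres to cm^3); multiplying by 100 converts cm^2 to mm^2.
    """
    if epsilon_m_cm <= 0:
        raise BudgetError("extinction coefficient must be positive")
    import math

    sigma_cm2 = math.log(10.0) * epsilon_m_cm * 1000.0 / AVOGADRO
    return sigma_cm2 * 100.0


def photons_per_molecule(spec: ExcitationSpec) -> float:
    """Mean photons absorbed per chromophore for an excitation specification."""
    fluence = photon_fluence(spec.pulse_fluence, spec.wavelength)
    return fluence * cross_section(spec.epsilon) / spec.attenuation_factor


def budget_table(spec: ExcitationSpec) -> dict[str, float]:
    """All four chain quantities as a labeled dictionary (for reports and the CLI)."""
    return {
        "photon_energy_J": photon_energy(spec.wavelength),
        "photon_fluence_per_mm2": photon_fluence(spec.pulse_fluence, spec.wavelength),
        "cross_section_mm2": cross_section(spec.epsilon),
        "photons_per_molecule": photons_per_molecule(spec),
    }
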