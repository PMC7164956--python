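"""Photon-budget arithmetic for a pump-probe excitation scheme.

Given the pump wavelength, the pulse fluence at the sample and the
chromophore's extinction coefficient, chain through photon energy, photon
fluence, absorption cross-section and mean photons absorbed per molecule.
"""

from trxdiff.photon_budget import ExcitationSpec, budget_table

# a red pump pulse on a bilin-type chromophore: 640 nm, 1.7 mJ/mm^2,
# epsilon = 27.7e3 1/(M cm)
spec = ExcitationSpec(wavelength=640.0, pulse_fluence=1.7, epsilon=27.7e3)

print("Without attenuation:")
for key, value in budget_table(spec).items():
    print(f"  {key:28s} {value:.4g}")

# a scattering carrier medium (e.g. a grease jet) can attenuate the pump;
# an attenuation factor of 5 reduces the absorbed photons accordingly
attenuated = ExcitationSpec(
    wavelength=640.0, pulse_fluence=1.7, epsilon=27.7e3, attenuation_factor=5.0
)
print("\nWith 5x attenuation:")
print(f"  photons_per_molecule         {budget_table(attenuated)['photons_per_molecule']:.4g}")
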