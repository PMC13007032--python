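"""Physical constants and unit conversions.

Internal units throughout the package: length in angstrom (Å), energy in
kJ mol⁻¹, temperature in kelvin, mass in g mol⁻¹, charge in elementary
charges, density in g cm⁻³.
"""

#: Boltzmann constant in kJ mol⁻¹ K⁻¹.
KB = 0.0083144621

#: kcal → kJ conversion factor.
KCAL_TO_KJ = 4.184

#: Avogadro's number, mol⁻¹.
AVOGADRO = 6.02214076e23

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Default umbrella force constant, kJ mol⁻¹ Å⁻² (= 10 kcal mol⁻¹ Å⁻²).
DEFAULT_FORCE_CONSTANT = 10.0 * KCAL_TO_KJ


def kT(temperature: float) -> float:
    """Thermal energy k_B·T in kJ mol⁻¹."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
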