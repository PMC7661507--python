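"""Physical constants and unit conversions used across the package.

Internal unit system: molar (M) for concentrations, seconds for time,
nm and kJ/mol for structural free-energy profiles.  Conversions between
the file-level units (nM, µM, G/cm, ppm, ...) and the internal system are
centralized here so that no module carries its own powers of ten.
"""

# Boltzmann constant in kJ mol^-1 K^-1 (i.e., the molar gas constant R)
KB_KJ_MOL_K = 0.008314462618

#: Avogadro constant, mol^-1
N_AVOGADRO = 6.02214076e23

#: litres per cubic nanometre
LITRE_PER_NM3 = 1e-24

#: nm^2 per cm^2 (diffusion-coefficient conversion)
NM2_PER_CM2 = 1e14

#: 15N gyromagnetic ratio used in pulsed-field-gradient fits, rad G^-1 s^-1
GAMMA_PFG = 26752.0

#: hydrodynamic radius of 1,4-dioxane, the internal viscosity reference, in Å
RH_DIOXANE_ANGSTROM = 2.12

# concentration unit multipliers to molar
MOLAR_UNITS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def to_molar(value: float, unit: str) -> float:
    """Convert a concentration in `unit` (e.g. 'nM') to molar."""
    try:
        return value * MOLAR_UNITS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None
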