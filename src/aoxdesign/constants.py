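"""Physical constants and unit conversions used throughout the package.

All thermochemistry is handled in kcal/mol, temperatures in kelvin,
concentrations on the 1 M standard state, viscosities in Pa·s and radii in
ångström.  Every conversion between these units lives here so that no module
carries its own copy of a constant.
"""

from __future__ import annotations

# CODATA 2018
KB_J = 1.380649e-23           # Boltzmann constant, J/K
H_J = 6.62607015e-34          # Planck constant, J·s
NA = 6.02214076e23            # Avogadro constant, 1/mol
C_CM = 2.99792458e10          # speed of light, cm/s

R_KCAL = 1.987204259e-3       # gas constant, kcal/(mol·K)
#: Gas-constant value the inhibition-constant convention uses (3 significant
#: figures beyond the leading digit, matching common docking post-processing).
R_KCAL_KI = 1.9872e-3

KCAL_TO_J_PER_MOL = 4184.0
ANGSTROM = 1e-10              # m

T_DEFAULT = 298.15            # K
PH_DEFAULT = 7.4

#: Dynamic viscosities at 298.15 K, Pa·s.
VISCOSITY_WATER = 8.91e-4
VISCOSITY_LIPID = 8.62e-4     # pentyl ethanoate, a lipid-mimetic solvent

#: Literature acid constant of the hydroperoxyl radical (HO2•/O2•−).
PKA_HYDROPEROXYL = 4.8


def kbt_over_h(T: float) -> float:
    """Frequency prefactor k_B·T/h in s⁻¹ (6.21e12 at 298.15 K)."""
    return KB_J * T / H_J


def rt_kcal(T: float) -> float:
    """R·T in kcal/mol."""
    return R_KCAL * T


def rt_ln10_kcal(T: float) -> float:
    """R·T·ln(10) in kcal/mol — 1.364 kcal/mol per pH (or pKa) unit at 298.15 K."""
    import math

    return R_KCAL * T * math.log(10.0)


def wavenumber_to_energy_kcal(nu_cm: float) -> float:
    """Convert a vibrational wavenumber (cm⁻¹) to an energy in kcal/mol."""
    return H_J * C_CM * nu_cm * NA / KCAL_TO_J_PER_MOL
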