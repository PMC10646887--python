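"""Unit system and physical constants.

Internal units are fixed throughout the package: lengths in Å, time in ps,
mass in amu, charge in elementary charges, energy in kcal mol⁻¹.  Inputs
quoted in GROMACS conventions (nm, kJ mol⁻¹) are converted at the boundary.
"""

# energy
KCAL_PER_KJ = 1.0 / 4.184
KJ_PER_KCAL = 4.184

# length
ANGSTROM_PER_NM = 10.0

#: Boltzmann constant / gas constant per mole, kcal mol⁻¹ K⁻¹
KB_KCAL_MOL_K = 1.98720425864e-3

#: Coulomb prefactor in CHARMM convention, Å·kcal mol⁻¹ e⁻²
COULOMB_KCAL = 332.0637


def kj_mol_nm2_to_kcal_mol_A2(k: float) -> float:
    """Convert a harmonic force constant from kJ mol⁻¹ nm⁻² to kcal mol⁻¹ Å⁻²."""
    return k * KCAL_PER_KJ / ANGSTROM_PER_NM**2


def nm_to_A(x: float) -> float:
    return x * ANGSTROM_PER_NM


def kBT(temperature: float) -> float:
    """Thermal energy in kcal mol⁻¹ at the given temperature (K)."""
    return KB_KCAL_MOL_K * temperature


#: umbrella bias force constant used throughout: 1000 kJ mol⁻¹ nm⁻²
BIAS_K_DEFAULT = kj_mol_nm2_to_kcal_mol_A2(1000.0)

#: umbrella window spacing: 0.1 nm
WINDOW_SPACING_DEFAULT = nm_to_A(0.1)

#: simulation temperature (K)
TEMPERATURE_DEFAULT = 303.0
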