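"""Physical constants and unit conversions.

Internal conventions: lengths in Å, energies in kJ/mol, times in ps.
Reaction-coordinate and spring-constant interfaces that follow the
umbrella-sampling literature accept nm and kJ/mol/nm² and convert.
"""

#: Boltzmann constant, kJ mol⁻¹ K⁻¹ (CODATA).
KB_KJ_PER_MOL_K = 0.008314462618

#: Coulomb prefactor f = 1/(4πε₀) in kJ mol⁻¹ nm e⁻².
COULOMB_CONSTANT_KJ_NM_E2 = 138.935458

#: Å per nm.
A_PER_NM = 10.0

#: Bondi van der Waals radii in Å, keyed by element symbol.  Used as the
#: element-level fallback when a parameter table carries no entry for an
#: atom; any table entry overrides these.
BONDI_RADII_A = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "MG": 1.73,
    "K": 2.75,
    "NA": 2.27,
    "ZN": 1.39,
}


def kt_kj_per_mol(temperature_k: float) -> float:
    """Thermal energy kT in kJ/mol at the given temperature in kelvin."""
    return KB_KJ_PER_MOL_K * temperature_k
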