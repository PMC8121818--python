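"""Physical constants and unit conversions.

Internal units throughout the package: length nm, time ps, mass amu,
temperature K, energy kcal/mol (amu·nm²/ps² at intermediate steps).
One amu·nm²/ps² equals exactly 1 kJ/mol.
"""

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Avogadro's number, mol^-1.
N_AVOGADRO = 6.02214e23

#: Boltzmann constant in internal energy units, amu·nm²·ps^-2·K^-1 (= kJ/mol/K).
KB_INTERNAL = 8.31446e-3

#: kJ per kcal.
KJ_PER_KCAL = 4.184

#: amu·nm²/ps² (= kJ/mol) expressed in kcal/mol.
INTERNAL_TO_KCAL = 1.0 / KJ_PER_KCAL

#: One atmosphere in pascal.
PA_PER_ATM = 101325.0

#: One amu in kg.
KG_PER_AMU = 1.66053906892e-27

#: nm/ps in m/s.
M_S_PER_NM_PS = 1.0e3

#: nm²/ps in cm²/s.
CM2_S_PER_NM2_PS = 1.0e-2

#: nm³ in liters.
LITER_PER_NM3 = 1.0e-24


def kinetic_temperature(kinetic_energy_internal: float, n_dof: int) -> float:
    """Instantaneous temperature from total kinetic energy (amu·nm²/ps²)."""
    if n_dof <= 0:
        raise ValueError("n_dof must be positive")
    return 2.0 * kinetic_energy_internal / (n_dof * KB_INTERNAL)
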