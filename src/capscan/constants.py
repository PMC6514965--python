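"""Physical constants in the kcal/mol - Angstrom - elementary-charge unit system."""

#: Coulomb constant, kcal*A/(mol*e^2).  332.0636*q1*q2/r is the interaction
#: energy in kcal/mol of two charges (in e) r Angstroms apart in vacuum.
COULOMB_KCAL = 332.0636

#: Boltzmann constant, kcal/(mol*K).
KB_KCAL = 1.987204259e-3

#: Avogadro-derived conversion: mol/L -> particles/A^3.
MOLAR_TO_PER_A3 = 6.02214076e-4

#: Default temperature, K.
T_DEFAULT = 298.15


def kt_kcal(temperature: float = T_DEFAULT) -> float:
    """Thermal energy kT in kcal/mol at the given temperature."""
    return KB_KCAL * temperature


def debye_kappa(ionic_strength: float, eps_solvent: float = 80.0,
                temperature: float = T_DEFAULT) -> float:
    """Inverse Debye length kappa in 1/Angstrom.

    ``kappa^2 = 8 pi k_C n / (eps kT)`` with the ion number density ``n`` for a
    1:1 electrolyte of the given ionic strength (mol/L).  At 0.15 M, 298.15 K in
    water (eps 80) this gives a Debye length of ~7.9 A.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return 0.0
    import math
    n = ionic_strength * MOLAR_TO_PER_A3
    kappa2 = 8.0 * math.pi * COULOMB_KCAL * n / (eps_solvent * kt_kcal(temperature))
    return math.sqrt(kappa2)
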