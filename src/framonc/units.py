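"""Unit conventions and physical constants.

All public interfaces use a single unit system:

* length — ångström (Å)
* energy — kJ·mol⁻¹
* temperature — kelvin (K)
* pressure — bar
* charge — elementary charge (e)
* mass — g·mol⁻¹

Conversions between these are centralized here so that every estimator and
acceptance rule shares the same constants.
"""

#: Gas constant, kJ·mol⁻¹·K⁻¹.
R_GAS = 8.31446e-3

#: 1 bar·Å³ expressed in kJ·mol⁻¹ (per simulation box, i.e. multiplied by
#: Avogadro's number: 1e5 Pa · 1e-30 m³ · 6.02214e23 mol⁻¹ · 1e-3 kJ/J).
BAR_A3_TO_KJ_PER_MOL = 6.02214e-5

#: Coulomb prefactor e²/(4πε₀) in kJ·mol⁻¹·Å·e⁻².
COULOMB_K = 1389.35458

#: Avogadro constant, mol⁻¹ (used for g·cm⁻³ densities from Å³ volumes).
N_AVOGADRO = 6.02214076e23

#: Conversion factor: (g·mol⁻¹) / (Å³) → g·cm⁻³, i.e. 1/N_A · 1e24.
MASS_PER_A3_TO_G_PER_CM3 = 1.0e24 / N_AVOGADRO

ATOMIC_MASSES = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Br": 79.904, "I": 126.90, "Kr": 83.798, "Xe": 131.29,
}

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Br": 35, "I": 53,
    "Kr": 36, "Xe": 54,
}
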