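"""Physical constants and unit conversions (CODATA 2018).

Angles are handled in degrees at the API surface and radians internally;
energies in kcal/mol; masses in amu; lengths in Å; times in ps;
frequencies in GHz.
"""

#: Boltzmann constant in kcal mol^-1 K^-1 (R / 4184).
KB_KCAL_PER_MOL_K = 0.0019872043

#: One kcal/mol per molecule, in joule: 4184 / N_A.
KCAL_PER_MOL_IN_J = 6.947695e-21

#: One amu·Å² in kg·m²: 1.66053907e-27 kg × 1e-20 m².
AMU_A2_IN_KG_M2 = 1.66053907e-47


def kbt_kcal_per_mol(temperature_k: float) -> float:
    """Thermal energy k_B·T in kcal/mol at the given temperature (K)."""
    return KB_KCAL_PER_MOL_K * temperature_k
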