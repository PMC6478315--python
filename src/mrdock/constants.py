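"""Physical constants (AMBER conventions).

Units throughout the package: Å for lengths, kcal/mol for energies, elementary
charges for partial charges, Kelvin for temperature.  Angles are degrees at
user-facing surfaces (move sizes, torsions) and radians internally.
"""

#: Boltzmann constant, kcal/mol/K.
BOLTZMANN_KCAL = 0.0019872041

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_KCAL = 332.0636

#: Atomic masses (amu) for the elements the package handles.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
}


def atomic_mass(element: str) -> float:
    """Mass in amu for an element symbol (case-insensitive)."""
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {element!r}") from None
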