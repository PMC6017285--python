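"""Physical constants and unit conventions.

Internal units: lengths in Å, charges in elementary charge e, masses in
amu, energies in kcal/mol, time in fs.  Reports use ps for time.
"""

#: Coulomb constant in kcal·Å/(mol·e²) — divides by the relative
#: dielectric constant of the continuum solvent.
COULOMB = 332.0637

#: Boltzmann constant in kcal/(mol·K).
KB = 1.9872041e-3

#: Conversion from kcal/(mol·Å·amu) to acceleration in Å/fs².
#: Derived from 1 kcal/mol = 4184 J/mol, 1 amu·NA = 1e-3 kg/mol.
KCAL_PER_MOL_TO_AMU_A2_FS2 = 4.184e-4

#: Default process temperature (K).
DEFAULT_TEMPERATURE = 293.0

#: Relative dielectric constants for common continuum solvents.
EPSILON_WATER = 80.0
EPSILON_ETHANOL = 26.0

#: Atomic masses (amu) for the elements this package handles.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.904,
    # Generic toy-site element: a carbon-like pseudo-atom.
    "X": 12.011,
}


def kBT(temperature: float) -> float:
    """Thermal energy kB·T in kcal/mol."""
    return KB * temperature
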