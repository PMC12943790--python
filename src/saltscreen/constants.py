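"""Physical constants and atomic weights used throughout the package.

All temperatures are kelvin internally; Celsius appears only at I/O
boundaries.  Enthalpies of fusion are J/mol internally.
"""

#: Molar gas constant, J/(mol K).  Fixed at the rounded CODATA value so that
#: computed eutectic compositions are stable across environments.
R = 8.314

#: Additive offset between Celsius and kelvin scales.
CELSIUS_OFFSET = 273.15

#: IUPAC 2021 conventional atomic weights (g/mol) for the elements commonly
#: encountered in small-molecule salts and co-crystals.  Embedded as a
#: constant table: the downstream thermodynamics is insensitive at the
#: ~0.05 g/mol level, so an external data source would add nothing.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "He": 4.003,
    "Li": 6.94,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Zn": 65.38,
    "Br": 79.904,
    "I": 126.904,
}


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin: float) -> float:
    return t_kelvin - CELSIUS_OFFSET
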