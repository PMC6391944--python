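"""Small chemistry helpers: molar masses from molecular formulas and solvent data.

Molar masses are always recomputed from formulas with standard atomic
weights rather than hard-coded, so downstream throughput arithmetic
(g/h, g/mL/h, doses/day) stays traceable to the formula of each compound.
"""

from __future__ import annotations

import re

# IUPAC 2021 standard atomic weights (conventional values), g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Br": 79.904,
    "I": 126.904,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol of a Hill-notation molecular formula, e.g. ``C10H12ClNO``."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"malformed molecular formula: {formula!r}")
    mass = 0.0
    for element, count in _FORMULA_TOKEN.findall(formula):
        if element not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {element!r} in {formula!r}")
        mass += ATOMIC_WEIGHTS[element] * (int(count) if count else 1)
    return mass


# Liquid molar volumes (mL/mol) at ~25 degC from molar mass / density; used for
# the ideal-volume-additivity stream model in the telescoped mass balance.
SOLVENTS: dict[str, dict[str, float]] = {
    "dcm": {"molar_mass": molar_mass("CH2Cl2"), "density": 1.3266},
    "nmp": {"molar_mass": molar_mass("C5H9NO"), "density": 1.028},
    "water": {"molar_mass": molar_mass("H2O"), "density": 0.997},
}


def molar_volume(solvent: str) -> float:
    """Liquid molar volume of a known solvent, mL/mol."""
    try:
        data = SOLVENTS[solvent]
    except KeyError:
        raise KeyError(f"unknown solvent {solvent!r}; known: {sorted(SOLVENTS)}") from None
    return data["molar_mass"] / data["density"]
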