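"""Monoisotopic mass arithmetic for small-molecule annotation.

All adduct and neutral-loss rules in the annotation module reduce to sums of
monoisotopic atomic masses. Ion m/z values account for the electron mass
(0.00055 Da, well below the default 0.005 Da tolerance but kept for
correctness).
"""

from __future__ import annotations

import re

#: Monoisotopic atomic masses (Da) of the elements occurring in plant defense
#: metabolites handled here (CODATA/AME-derived standard values).
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "Na": 22.9897692809,
}

ELECTRON_MASS = 0.00054857990907

#: Mass added to a neutral molecule M to obtain the [M+H]+ ion m/z.
PROTON_MASS = MONOISOTOPIC["H"] - ELECTRON_MASS

#: m/z spacing between the [M+Na]+ and [M+H]+ adducts of one molecule
#: (mass(Na) - mass(H); the electron term cancels). Rounds to 21.98.
NA_H_SPACING = MONOISOTOPIC["Na"] - MONOISOTOPIC["H"]

#: Neutral mass shift of an O-acetylation (+C2H2O). Rounds to 42.011.
ACETYL_MASS = 2 * MONOISOTOPIC["C"] + 2 * MONOISOTOPIC["H"] + MONOISOTOPIC["O"]

#: Neutral mass shift of an O-formylation (+CHO-H, i.e. +CO).
FORMYL_MASS = MONOISOTOPIC["C"] + MONOISOTOPIC["O"]

#: Neutral loss of one water molecule.
WATER_MASS = 2 * MONOISOTOPIC["H"] + MONOISOTOPIC["O"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass (Da) of a neutral elemental formula.

    Parameters
    ----------
    formula : str
        Hill-style formula over the supported elements, e.g. ``"C23H34O4"``.

    Returns
    -------
    float
        Sum of monoisotopic atomic masses.

    Raises
    ------
    ValueError
        If the formula contains an unsupported element or is malformed.
    """
    if not formula or not isinstance(formula, str):
        raise ValueError(f"empty or non-string formula: {formula!r}")
    pos = 0
    total = 0.0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        element, count = match.groups()
        if element not in MONOISOTOPIC:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        total += MONOISOTOPIC[element] * (int(count) if count else 1)
        pos = match.end()
        if pos == len(formula):
            break
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r} at position {pos}")
    return total


def mz_mh_pos(neutral_mass: float) -> float:
    """m/z of the [M+H]+ adduct."""
    return neutral_mass + PROTON_MASS


def mz_mna_pos(neutral_mass: float) -> float:
    """m/z of the [M+Na]+ adduct."""
    return neutral_mass + MONOISOTOPIC["Na"] - ELECTRON_MASS


def mz_mh_neg(neutral_mass: float) -> float:
    """m/z of the [M-H]- adduct."""
    return neutral_mass - PROTON_MASS


def neutral_from_mh_pos(mz: float) -> float:
    """Neutral mass implied by an [M+H]+ ion."""
    return mz - PROTON_MASS


def neutral_from_mh_neg(mz: float) -> float:
    """Neutral mass implied by an [M-H]- ion."""
    return mz + PROTON_MASS
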