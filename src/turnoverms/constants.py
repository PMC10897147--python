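"""Embedded isotope mass and abundance constants.

Single source of truth for elemental isotope data (IUPAC-style monoisotopic
masses and representative natural abundances), amino-acid residue formulas and
built-in modifications.  Both the production envelope-convolution path and any
enumeration oracle must read from this table so that comparisons test the
algorithm, not the constants.
"""

from __future__ import annotations

PROTON_MASS = 1.007276

# element -> list of (monoisotopic mass, natural abundance), lightest first.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.00335484, 0.0107)],
    "H": [(1.00782503, 0.999885), (2.01410178, 0.000115)],
    "N": [(14.00307401, 0.99636), (15.00010890, 0.00364)],
    "O": [(15.99491462, 0.99757), (16.99913176, 0.00038), (17.99915961, 0.00205)],
    "S": [
        (31.97207117, 0.9499),
        (32.97145891, 0.0075),
        (33.96786701, 0.0425),
        (35.96708071, 0.0001),
    ],
}

C13_MASS = ISOTOPES["C"][1][0]
N15_MASS = ISOTOPES["N"][1][0]
# single-neutron mass differences used throughout
N15_SHIFT = N15_MASS - ISOTOPES["N"][0][0]  # 0.99703489 Da
C13_SHIFT = C13_MASS - ISOTOPES["C"][0][0]  # 1.00335484 Da
# a 13C6-lysine carries six heavy carbons
LYS_C13_SHIFT = 6 * C13_SHIFT  # 6.02012904 Da

# residue formulas (peptide-bond residues; add one water per peptide)
AA_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER = {"H": 2, "O": 1}


def monoisotopic_mass(formula: dict[str, int]) -> float:
    """Lightest-isotope mass of an elemental formula."""
    return sum(n * ISOTOPES[el][0][0] for el, n in formula.items())
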