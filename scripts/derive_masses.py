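"""Derive the hard-coded monoisotopic mass constants from atomic masses.

Run: python scripts/derive_masses.py
Prints the values frozen into glyccomp.composition.MassConstants.
"""

# IUPAC/CODATA monoisotopic atomic masses (Da)
ATOMS = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

FORMULAS = {
    "m_dhexa": {"C": 6, "H": 6, "O": 5},
    "m_dhexa_anhydro": {"C": 6, "H": 4, "O": 4},
    "m_hexa": {"C": 6, "H": 8, "O": 6},
    "m_glcn": {"C": 6, "H": 11, "N": 1, "O": 4},
    "m_ac": {"C": 2, "H": 2, "O": 1},
    "m_so3": {"S": 1, "O": 3},
    "m_h2o": {"H": 2, "O": 1},
    "m_nh3": {"N": 1, "H": 3},
}


def formula_mass(counts: dict[str, int]) -> float:
    return sum(ATOMS[el] * n for el, n in counts.items())


if __name__ == "__main__":
    for name, counts in FORMULAS.items():
        print(f"{name} = {formula_mass(counts)!r}")
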