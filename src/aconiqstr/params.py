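"""Per-element force-field and electronegativity parameters.

Lennard-Jones radii/well depths follow the Tripos force-field values used by
classical molecular-field analysis; PEOE (partial equalization of orbital
electronegativity) coefficients are the Gasteiger-Marsili a, b, c polynomial
coefficients, keyed on element and hybridization.
"""

from __future__ import annotations

# vdW radius (Angstrom), well depth (kcal/mol) per element.
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.20, 0.042),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "P": (1.80, 0.314),
    "S": (1.80, 0.314),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
    "I": (1.98, 0.623),
}

# Default CoMFA probe: sp3 carbon, +1 charge (Tripos convention).
PROBE_RADIUS = 1.70
PROBE_EPSILON = 0.107
PROBE_CHARGE = 1.0

COULOMB_CONSTANT = 332.06  # kcal * Angstrom / (mol * e^2)

# Gasteiger-Marsili chi(q) = a + b q + c q^2 coefficients.
# Keys: (element, hybridization); hybridization in {"sp3", "sp2", "sp", ""}.
PEOE_PARAMS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("H", ""): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", ""): (14.66, 13.85, 2.31),
    ("Cl", ""): (11.00, 9.69, 1.35),
    ("Br", ""): (10.08, 8.47, 1.16),
    ("I", ""): (9.90, 7.96, 0.96),
    ("S", "sp3"): (10.14, 9.13, 1.38),
    ("S", "sp2"): (10.88, 9.49, 1.33),
    ("P", "sp3"): (8.90, 8.24, 0.96),
}

# Cation electronegativity chi+ used as the charge-transfer normalizer.
# Hydrogen is special-cased (Gasteiger-Marsili use 20.02 instead of a+b+c).
PEOE_H_CATION = 20.02

PEOE_ITERATIONS = 6
PEOE_DAMPING = 0.5


def peoe_coefficients(element: str, hybridization: str) -> tuple[float, float, float]:
    """Look up PEOE coefficients, falling back across hybridization states."""
    for hyb in (hybridization, "sp3", "sp2", "sp", ""):
        key = (element, hyb)
        if key in PEOE_PARAMS:
            return PEOE_PARAMS[key]
    raise KeyError(element)
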