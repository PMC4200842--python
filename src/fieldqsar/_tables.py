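"""Atomic parameter tables used throughout the field and charge machinery.

Every table here is a package default and is overridable at the call sites
that consume it; reports record a hash of the effective tables so results
remain attributable to a concrete parameterization.
"""

from __future__ import annotations

import hashlib
import json

# Bondi van der Waals radii, Å.
BONDI_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
}

# Lennard-Jones well depths (kcal/mol) per element, Tripos-style magnitudes.
# Zero-crossing sigma is derived from the Bondi radius: the pair minimum sits
# at the sum of radii, so sigma_elem = 2 * r_vdw * 2**(-1/6).
LJ_EPSILON: dict[str, float] = {
    "H": 0.042,
    "C": 0.107,
    "N": 0.095,
    "O": 0.116,
    "F": 0.109,
    "P": 0.314,
    "S": 0.314,
    "Cl": 0.314,
    "Br": 0.434,
    "I": 0.623,
}

_SIGMA_FROM_RMIN = 2.0 ** (-1.0 / 6.0)


def lj_sigma(element: str, radii: dict[str, float] | None = None) -> float:
    """LJ zero-crossing distance for a single element, Å."""
    r = (radii or BONDI_VDW_RADII)[element]
    return 2.0 * r * _SIGMA_FROM_RMIN


# PEOE (a, b, c) electronegativity coefficients in eV, keyed by
# (element, hybridization); chi(q) = a + b q + c q^2.  Gasteiger 1980 set.
PEOE_PARAMS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("H", "s"): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", "sp3"): (14.66, 13.85, 2.31),
    ("Cl", "sp3"): (11.00, 9.69, 1.35),
    ("Br", "sp3"): (10.08, 8.47, 1.16),
    ("I", "sp3"): (9.90, 7.96, 0.96),
    ("S", "sp3"): (10.14, 9.13, 1.38),
}

# Cation electronegativity chi(+1) = a + b + c, except hydrogen which uses
# the conventional fixed value 20.02 eV.
PEOE_H_CATION_CHI = 20.02

# Default atomic hydrophobicity weights for the CoMSIA hydrophobic field.
# Rule-based: apolar carbons and halogens positive, polar heteroatoms and
# their hydrogens negative.  Keys are rule names resolved in chem_io.
HYDROPHOBIC_TABLE: dict[str, float] = {
    "C_apolar": 1.0,       # carbon with no N/O/S neighbour
    "C_polar": 0.0,        # carbon bonded to N/O/S
    "halogen": 0.5,        # F, Cl, Br, I
    "N": -1.0,
    "O": -1.0,
    "S": 0.2,
    "P": 0.0,
    "H_on_polar": -0.5,    # hydrogen bonded to N/O
    "H_on_apolar": 0.0,
}


def table_hash(*tables: dict) -> str:
    """Stable short hash of parameter tables, recorded in reports."""
    blob = json.dumps([sorted((str(k), v) for k, v in t.items()) for t in tables])
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
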