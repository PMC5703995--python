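"""Physical constants, atomic radii and model-compound pKas.

Units throughout the package: lengths in angstrom, energies in kcal/mol,
charges in elementary charge units, temperatures in kelvin.
"""

from __future__ import annotations

# Coulomb constant e^2/(4 pi eps0) expressed in kcal mol^-1 A e^-2.
COULOMB_K = 332.06

# Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.9872041e-3

DEFAULT_TEMPERATURE = 298.15


def rt_kcal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """RT in kcal/mol."""
    return R_KCAL * temperature


def ln10_rt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """2.303*RT in kcal/mol — the free energy of one pKa unit."""
    return 2.303 * rt_kcal(temperature)


# Fixed van der Waals radius set (angstrom). Hydrogens are listed for
# completeness but crystal structures normally omit them; no united-atom
# inflation is applied.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}

DEFAULT_PROBE_RADIUS = 1.4

# Model-compound pKas of the titratable site types.  Tyrosine is deliberately
# absent: with a model pKa of 10.2 it is treated as a neutral polar hydroxyl
# group, contributing only through the OH background dipole.
MODEL_PKAS = {
    "ASP": 4.0,
    "GLU": 4.4,
    "LYS": 10.4,
    "ARG": 12.0,
    "HIS": 6.3,
    "CYS": 8.3,
    "NTERM": 7.5,
    "CTERM": 3.8,
}

# acid: ionised form is the deprotonated anion; base: ionised form is the
# protonated cation.
SITE_POLARITY = {
    "ASP": "acid",
    "GLU": "acid",
    "CYS": "acid",
    "CTERM": "acid",
    "LYS": "base",
    "ARG": "base",
    "HIS": "base",
    "NTERM": "base",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_AA3 = set(THREE_TO_ONE)
STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"

WATER_NAMES = {"HOH", "WAT", "DOD"}

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}
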