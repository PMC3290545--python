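"""Amino-acid code tables shared across the package.

Three naming systems appear in structures and text: full names
("aspartic acid"), 3-letter codes ("ASP") and 1-letter codes ("D").
All normalization funnels into the upper-case 3-letter code, which is
also the representation used by mmCIF ``auth_comp_id``.
"""

from __future__ import annotations

#: 20 standard amino acids, 3-letter -> 1-letter.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_CODES: frozenset[str] = frozenset(THREE_TO_ONE)

#: Full names and common variants, lower-case -> 3-letter code.
#: Plurals are handled by the patterns, not by this table.
NAME_TO_THREE: dict[str, str] = {
    "alanine": "ALA",
    "arginine": "ARG",
    "asparagine": "ASN",
    "aspartate": "ASP",
    "aspartic acid": "ASP",
    "cysteine": "CYS",
    "glutamine": "GLN",
    "glutamate": "GLU",
    "glutamic acid": "GLU",
    "glycine": "GLY",
    "histidine": "HIS",
    "isoleucine": "ILE",
    "leucine": "LEU",
    "lysine": "LYS",
    "methionine": "MET",
    "phenylalanine": "PHE",
    "proline": "PRO",
    "serine": "SER",
    "threonine": "THR",
    "tryptophan": "TRP",
    "tyrosine": "TYR",
    "valine": "VAL",
}

#: van der Waals radii in Angstrom, by element symbol (Bondi-style
#: values rounded to those in common molecular-surface codes).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "FE": 1.80, "ZN": 1.39, "MG": 1.73, "CA": 1.74,
    "MN": 1.73, "NA": 2.27, "K": 2.75, "CU": 1.40, "NI": 1.63,
}

DEFAULT_VDW = 1.70


def vdw_radius(element: str) -> float:
    """van der Waals radius for an element symbol (case-insensitive)."""
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def one_to_three(code: str) -> str | None:
    return ONE_TO_THREE.get(code.upper())


def name_to_three(name: str) -> str | None:
    """Normalize a full amino-acid name (any case) to a 3-letter code."""
    return NAME_TO_THREE.get(name.lower())
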