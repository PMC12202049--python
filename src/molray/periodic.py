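"""Per-element constants: van der Waals radii, covalent radii, display colors.

Radii are in Angstrom.  The van der Waals set is a Bondi-style compilation,
the covalent set a Cordero-style compilation; both are restricted to elements
that commonly occur in deposited structures.  Unknown elements fall back to
``VDW_FALLBACK`` / ``COVALENT_FALLBACK`` (a warning is logged by the radius
assignment code, not here).
"""

from __future__ import annotations

VDW_FALLBACK: float = 1.50
COVALENT_FALLBACK: float = 0.76

VDW_RADII: dict[str, float] = {
    "H": 1.20, "HE": 1.40,
    "LI": 1.82, "BE": 1.53, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52,
    "F": 1.47, "NE": 1.54,
    "NA": 2.27, "MG": 1.73, "AL": 1.84, "SI": 2.10, "P": 1.80, "S": 1.80,
    "CL": 1.75, "AR": 1.88,
    "K": 2.75, "CA": 2.31, "MN": 1.97, "FE": 1.94, "CO": 1.92, "NI": 1.63,
    "CU": 1.40, "ZN": 1.39, "GA": 1.87, "AS": 1.85, "SE": 1.90, "BR": 1.85,
    "KR": 2.02,
    "RB": 3.03, "SR": 2.49, "MO": 2.09, "RU": 2.07, "PD": 1.63, "AG": 1.72,
    "CD": 1.58, "IN": 1.93, "SN": 2.17, "SB": 2.06, "TE": 2.06, "I": 1.98,
    "XE": 2.16,
    "CS": 3.43, "BA": 2.68, "W": 2.10, "PT": 1.75, "AU": 1.66, "HG": 1.55,
    "TL": 1.96, "PB": 2.02, "BI": 2.07, "U": 1.86,
}

COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "HE": 0.28,
    "LI": 1.28, "BE": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "NE": 0.58,
    "NA": 1.66, "MG": 1.41, "AL": 1.21, "SI": 1.11, "P": 1.07, "S": 1.05,
    "CL": 1.02, "AR": 1.06,
    "K": 2.03, "CA": 1.76, "MN": 1.39, "FE": 1.32, "CO": 1.26, "NI": 1.24,
    "CU": 1.32, "ZN": 1.22, "GA": 1.22, "AS": 1.19, "SE": 1.20, "BR": 1.20,
    "KR": 1.16,
    "RB": 2.20, "SR": 1.95, "MO": 1.54, "RU": 1.46, "PD": 1.39, "AG": 1.45,
    "CD": 1.44, "IN": 1.42, "SN": 1.39, "SB": 1.39, "TE": 1.38, "I": 1.39,
    "XE": 1.40,
    "CS": 2.44, "BA": 2.15, "W": 1.62, "PT": 1.36, "AU": 1.36, "HG": 1.32,
    "TL": 1.45, "PB": 1.46, "BI": 1.48, "U": 1.96,
}

# CPK-style display colors, RGBA 0-255.  Fallback is pink.
COLOR_FALLBACK: tuple[int, int, int, int] = (255, 105, 180, 255)

ELEMENT_COLORS: dict[str, tuple[int, int, int, int]] = {
    "H": (255, 255, 255, 255),
    "C": (144, 144, 144, 255),
    "N": (48, 80, 248, 255),
    "O": (255, 13, 13, 255),
    "S": (255, 255, 48, 255),
    "P": (255, 128, 0, 255),
    "F": (144, 224, 80, 255),
    "CL": (31, 240, 31, 255),
    "BR": (166, 41, 41, 255),
    "I": (148, 0, 148, 255),
    "HE": (217, 255, 255, 255),
    "NA": (171, 92, 242, 255),
    "MG": (138, 255, 0, 255),
    "K": (143, 64, 212, 255),
    "CA": (61, 255, 0, 255),
    "MN": (156, 122, 199, 255),
    "FE": (224, 102, 51, 255),
    "NI": (80, 208, 80, 255),
    "CU": (200, 128, 51, 255),
    "ZN": (125, 128, 176, 255),
    "SE": (255, 161, 0, 255),
}

# Elements whose two-letter symbol may be confused with a one-letter element
# followed by a remoteness indicator when inferring the element from a PDB
# atom name (e.g. "CA" calcium vs. an alpha carbon).
TWO_LETTER_ELEMENTS: frozenset[str] = frozenset(VDW_RADII) - frozenset("HBCNOFPSKIWU")


def normalize_element(symbol: str) -> str:
    """Canonical upper-case element symbol, stripped of charge decorations."""
    return symbol.strip().upper().rstrip("+-0123456789")
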