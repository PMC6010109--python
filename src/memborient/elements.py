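"""Packaged element table: atomic masses and van der Waals radii.

Masses in Da (standard atomic weights), radii in Å (Bondi-style vdW radii,
the set commonly used for solvent-accessible-surface calculations). Keeping
the table in the package means no structure ever needs a network lookup.
"""

from __future__ import annotations

#: element symbol -> (mass [Da], vdW radius [Å])
ELEMENT_TABLE: dict[str, tuple[float, float]] = {
    "H": (1.008, 1.20),
    "C": (12.011, 1.70),
    "N": (14.007, 1.55),
    "O": (15.999, 1.52),
    "S": (32.06, 1.80),
    "P": (30.974, 1.80),
    "F": (18.998, 1.47),
    "CL": (35.45, 1.75),
    "BR": (79.904, 1.85),
    "I": (126.904, 1.98),
    "NA": (22.990, 2.27),
    "K": (39.098, 2.75),
    "MG": (24.305, 1.73),
    "CA": (40.078, 2.31),
    "ZN": (65.38, 1.39),
    "FE": (55.845, 2.00),
    "SE": (78.971, 1.90),
}

#: fallback for elements missing from the table
DEFAULT_MASS = 12.011
DEFAULT_RADIUS = 1.70


def element_from_name(name: str) -> str:
    """Guess an element symbol from a PDB-style atom name.

    Uses the first alphabetic character ("CA" -> C, "1HB" -> H); two-letter
    symbols are only returned when the full stripped name matches a known
    two-letter element (so a calcium ion named "CA" in an ion residue must
    carry an explicit element field to be distinguished from a Cα carbon).
    """
    stripped = name.strip().upper()
    if stripped in ELEMENT_TABLE and len(stripped) == 2 and not stripped[0].isdigit():
        # ambiguous two-letter names (CA, NA ...) default to the organic
        # single-letter reading when it exists
        if stripped[0] in ELEMENT_TABLE:
            return stripped[0]
        return stripped
    for ch in stripped:
        if ch.isalpha():
            return ch
    return ""


def mass_radius(element: str, default_radius: float = DEFAULT_RADIUS) -> tuple[float, float, bool]:
    """Return (mass, radius, known) for an element symbol."""
    key = element.strip().upper()
    if key in ELEMENT_TABLE:
        m, r = ELEMENT_TABLE[key]
        return m, r, True
    return DEFAULT_MASS, default_radius, False
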