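"""Element lookup tables: masses, van der Waals radii, name -> element rules.

The tables cover the elements that occur in protein/glycan structures and in
the monovalent-salt systems analysed here; the radii are the Bondi set.
"""

from __future__ import annotations

# Standard atomic masses (u), CIAAW abridged values.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "K": 39.098,
    "F": 18.998,
    "CL": 35.45,
    "CU": 63.546,
}

# Bondi van der Waals radii (A); conventional default when no set is stated.
VDW_RADIUS: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "NA": 2.27,
    "K": 2.75,
    "CU": 1.40,
}

# Two-letter element symbols that can appear as the first characters of an
# atom name in protein/salt systems.  Checked before the one-letter fallback.
_TWO_LETTER = ("CL", "NA", "CU", "BR", "FE", "ZN", "MG", "MN")


def element_from_name(name: str, resname: str = "") -> str:
    """Infer the element symbol from a PDB atom name.

    The rule is the standard PDB convention: strip digits and primes, try a
    two-letter symbol for ion/metal names (only outside amino-acid residues,
    where e.g. ``CA`` means the alpha carbon), else take the first letter.
    """
    stripped = name.strip().lstrip("0123456789")
    upper = stripped.upper().rstrip("0123456789'\"*")
    if not upper:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    from ._residues import AMINO_ACIDS  # local import to avoid cycle

    if resname.strip().upper() not in AMINO_ACIDS and upper[:2] in _TWO_LETTER:
        return upper[:2]
    return upper[0]


def mass_of(element: str) -> float:
    try:
        return ATOMIC_MASS[element.upper()]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {element!r}") from None


def vdw_radius_of(element: str) -> float:
    try:
        return VDW_RADIUS[element.upper()]
    except KeyError:
        raise KeyError(f"no vdW radius tabulated for element {element!r}") from None
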