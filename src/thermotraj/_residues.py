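"""Residue-level chemical knowledge used by topology perception."""

from __future__ import annotations

AMINO_ACIDS: frozenset[str] = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# Backbone atom names, including the amide hydrogen variants written by
# common builders.  OXT is terminal and handled separately.
BACKBONE_NAMES: frozenset[str] = frozenset({"N", "CA", "C", "O", "H", "HN", "HA", "H1", "H2", "H3"})

# Side-chain carboxylate oxygens of the acidic residues.
CARBOXYLATE_OXYGENS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# Side-chain nitrogens of the basic residues (protonated forms).
BASIC_NITROGENS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}

# Carbohydrate residue names treated as glycan; N-acetylglucosamine is the
# moiety present at N-glycosylation sites in the systems of interest.
DEFAULT_GLYCAN_RESNAMES: frozenset[str] = frozenset({"NAG"})
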