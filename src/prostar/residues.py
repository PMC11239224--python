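"""Canonical amino-acid chemistry tables.

Atom compositions and their order follow the wwPDB chemical-component
definitions (PDB format v3): backbone N, CA, C, O first, then the
side-chain atoms in component order.  The coordinate codec relies on this
ordering being fixed: given the residue sequence, atom names never need to
be stored, and every atom has a well-defined set of already-decoded
candidates for use as trilateration references.
"""

from __future__ import annotations

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: heavy atoms of the 20 canonical residues, in canonical encode order
RESIDUE_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("N", "CA", "C", "O", "CB"),
    "ARG": ("N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"),
    "ASP": ("N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"),
    "CYS": ("N", "CA", "C", "O", "CB", "SG"),
    "GLN": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"),
    "GLY": ("N", "CA", "C", "O"),
    "HIS": ("N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"),
    "LEU": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"),
    "LYS": ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"),
    "MET": ("N", "CA", "C", "O", "CB", "CG", "SD", "CE"),
    "PHE": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("N", "CA", "C", "O", "CB", "CG", "CD"),
    "SER": ("N", "CA", "C", "O", "CB", "OG"),
    "THR": ("N", "CA", "C", "O", "CB", "OG1", "CG2"),
    "TRP": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1",
            "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1",
            "CE2", "CZ", "OH"),
    "VAL": ("N", "CA", "C", "O", "CB", "CG1", "CG2"),
}

RESIDUE_NAMES: tuple[str, ...] = tuple(sorted(RESIDUE_ATOMS))
RESIDUE_INDEX: dict[str, int] = {r: i for i, r in enumerate(RESIDUE_NAMES)}

#: OXT may terminate the final residue of a chain
TERMINAL_OXYGEN = "OXT"

ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def element_of(atom_name: str) -> str:
    """Element symbol of a canonical amino-acid heavy atom.

    For the 20 canonical residues (plus OXT) the element is always the
    first character of the atom name: C, N, O or S.
    """
    return atom_name[0]


def is_backbone(atom_name: str) -> bool:
    """Backbone atoms for lossy-error classification: N, CA, C, O, OXT."""
    return atom_name in BACKBONE_ATOMS or atom_name == TERMINAL_OXYGEN
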