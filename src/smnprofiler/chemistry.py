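"""Residue chemistry tables shared by the detection and annotation modules.

Everything here is static amino-acid knowledge in PDB v3 nomenclature:
which side-chain groups are titratable and carry formal charge, which atoms
can donate or accept hydrogen bonds, van der Waals radii, and the
one-/three-letter code maps.
"""

from __future__ import annotations

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Titratable side-chain charged groups: res_type -> (polarity, member atoms).
#: Asp/Glu carboxylates are negative; the Lys ammonium, Arg guanidinium
#: nitrogens and His imidazole nitrogens are treated as positive (no pKa
#: prediction; His counts as charged at both ring nitrogens).
CHARGED_GROUPS: dict[str, tuple[str, tuple[str, ...]]] = {
    "ASP": ("negative", ("OD1", "OD2")),
    "GLU": ("negative", ("OE1", "OE2")),
    "LYS": ("positive", ("NZ",)),
    "ARG": ("positive", ("NE", "NH1", "NH2")),
    "HIS": ("positive", ("ND1", "NE2")),
}

#: Side-chain hydrogen-bond donor heavy atoms per residue type.  A donor is
#: usable only when a covalently bound hydrogen (same residue, < 1.3 A) is
#: present in the model.
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
}

#: Side-chain hydrogen-bond acceptor atoms per residue type.  His ring
#: nitrogens accept only when unprotonated (no bound hydrogen in the model).
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "MET": ("SD",),
}

#: His acceptor atoms that require the unprotonated check.
CONDITIONAL_ACCEPTORS = {("HIS", "ND1"), ("HIS", "NE2")}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}

#: Maximum donor-hydrogen covalent bond length (A) used to resolve which
#: hydrogen belongs to which donor heavy atom.
DH_COVALENT_CUTOFF = 1.3

# ---------------------------------------------------------------------------
# van der Waals radii (A), NACCESS/Chothia set: O 1.40, N 1.65, S 1.85,
# tetrahedral C 1.87, trigonal/aromatic C 1.76.  Used by the SASA module.
# ---------------------------------------------------------------------------

ELEMENT_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.80, "H": 1.00}
DEFAULT_RADIUS = 1.80

#: Trigonal / aromatic carbons that take the 1.76 A radius, keyed by
#: (res_type, atom name); the backbone carbonyl carbon "C" is trigonal in
#: every residue type.
_TRIGONAL_SIDECHAIN_C = {
    "ASP": ("CG",),
    "GLU": ("CD",),
    "ASN": ("CG",),
    "GLN": ("CD",),
    "ARG": ("CZ",),
    "HIS": ("CG", "CD2", "CE1"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}
TRIGONAL_CARBONS = {(res, atom) for res, atoms in _TRIGONAL_SIDECHAIN_C.items() for atom in atoms}


def vdw_radius(res_type: str, atom_name: str, element: str) -> float:
    """NACCESS-style van der Waals radius for one atom.

    Trigonal/aromatic carbons (backbone carbonyl C and the ring/planar
    side-chain carbons) get 1.76 A; all other carbons 1.87 A; other elements
    use the element table with a 1.80 A fallback.
    """
    if element == "C":
        if atom_name == "C" or (res_type, atom_name) in TRIGONAL_CARBONS:
            return 1.76
        return 1.87
    return ELEMENT_RADII.get(element, DEFAULT_RADIUS)


# ---------------------------------------------------------------------------
# One-letter residue chemistry classes for mutation impact annotation.
# ---------------------------------------------------------------------------

FORMAL_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1, "H": +1}
HYDROPHOBIC = {"A", "V", "L", "I", "M", "F", "W", "P"}
#: Residues whose side chain acts as an uncharged polar hydrogen-bond donor.
POLAR_DONORS = {"N", "Q", "S", "T", "Y", "C"}


def is_backbone(atom_name: str) -> bool:
    """True for backbone (including amide/alpha hydrogens) atom names."""
    return atom_name in BACKBONE_ATOMS
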