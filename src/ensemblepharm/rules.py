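"""Pharmacophore typing rule table, version 1.

Explicit, versioned residue-template rules used to assign annotation points
to protein site atoms read from multi-model PDB files (which carry no bond
block).  The table documents its own chemistry choices; it does not claim
equivalence with any proprietary perception scheme.

Point classes (before feature building):
    Don  hydrogen-bond donor heavy atom (N-H, O-H, S-H parent)
    Acc  hydrogen-bond acceptor (N/O with an available lone pair, not +)
    Cat  cation (protonated amine N, guanidinium C, imidazolium centroid)
    Ani  anion (carboxylate group centroid)
    Aro  aromatic ring centroid
    PiR  non-aromatic all-sp2 pi-ring centroid
    Hyd  hydrophobic atom (C/S with no attached heteroatom)
    HydA hydrophobic centroid of >=3 contiguous hydrophobic atoms

Rule kinds:
    ("atom", cls, [names])      one point per named atom present
    ("centroid", cls, [names])  one point at the centroid; fires only when
                                every named atom is present in the selection
Residues also carry a "hyd" atom-name list; each present atom yields a Hyd
point and, when >=3 are present, their centroid yields one HydA point.
"""

from __future__ import annotations

RULES_VERSION = 1

# feature radii in Angstrom
DEFAULT_RADII: dict[str, float] = {
    "Don": 1.2, "Acc": 1.2, "Cat": 1.2, "Ani": 1.2,
    "Aro": 1.4, "PiR": 1.4, "Hyd": 1.6, "HydA": 1.6,
    "Don|Acc": 1.2, "Don|Cat": 1.2, "Aro|PiR": 1.4, "Hyd|HydA": 1.6,
}

HYD_MERGE_DISTANCE = 1.0   # Hyd points closer than this are grouped
HYD_MAX_RADIUS = 3.0       # cap on a merged hydrophobic feature
OVERLAP_TOLERANCE = 0.5    # Don&Acc / Don&Cat / Aro&PiR co-location tolerance

FEATURE_CLASSES = (
    "Don", "Acc", "Cat", "Ani", "Aro", "Hyd",
    "Don|Acc", "Don|Cat", "Aro|PiR", "Hyd|HydA",
)

_BACKBONE_DON = ("atom", "Don", ["N"])
_BACKBONE_ACC = ("atom", "Acc", ["O", "OXT"])

# side-chain rules per standard residue; backbone rules added automatically
_SIDECHAIN: dict[str, list] = {
    "GLY": [],
    "ALA": [],
    "VAL": [],
    "LEU": [],
    "ILE": [],
    "PRO": [],
    "MET": [("atom", "Hyd", ["SD"])],
    "PHE": [("centroid", "Aro", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"])],
    "TYR": [("centroid", "Aro", ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]),
            ("atom", "Don", ["OH"]), ("atom", "Acc", ["OH"])],
    "TRP": [("centroid", "Aro", ["CG", "CD1", "NE1", "CE2", "CD2"]),
            ("centroid", "Aro", ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]),
            ("atom", "Don", ["NE1"])],
    "SER": [("atom", "Don", ["OG"]), ("atom", "Acc", ["OG"])],
    "THR": [("atom", "Don", ["OG1"]), ("atom", "Acc", ["OG1"])],
    "CYS": [("atom", "Don", ["SG"])],
    "ASN": [("atom", "Don", ["ND2"]), ("atom", "Acc", ["OD1"])],
    "GLN": [("atom", "Don", ["NE2"]), ("atom", "Acc", ["OE1"])],
    "ASP": [("atom", "Acc", ["OD1", "OD2"]),
            ("centroid", "Ani", ["CG", "OD1", "OD2"])],
    "GLU": [("atom", "Acc", ["OE1", "OE2"]),
            ("centroid", "Ani", ["CD", "OE1", "OE2"])],
    "LYS": [("atom", "Don", ["NZ"]), ("atom", "Cat", ["NZ"])],
    "ARG": [("atom", "Don", ["NE", "NH1", "NH2"]), ("atom", "Cat", ["CZ"])],
    # neutral His, delta tautomer: ND1 acceptor, NE2 donor
    "HIS": [("centroid", "Aro", ["CG", "ND1", "CD2", "CE1", "NE2"]),
            ("atom", "Acc", ["ND1"]), ("atom", "Don", ["NE2"])],
    # doubly protonated His (imidazolium)
    "HIP": [("centroid", "Aro", ["CG", "ND1", "CD2", "CE1", "NE2"]),
            ("centroid", "Cat", ["CG", "ND1", "CD2", "CE1", "NE2"]),
            ("atom", "Don", ["ND1", "NE2"])],
}

# hydrophobic atom lists: C/S atoms with no bonded heteroatom in the template
_HYD_ATOMS: dict[str, list[str]] = {
    "ALA": ["CB"],
    "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "PRO": ["CB", "CG"],
    "MET": ["CB"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"],
    "TRP": ["CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"],
    "THR": ["CG2"],
    "LYS": ["CB", "CG", "CD"],
    "ARG": ["CB", "CG"],
    "GLN": ["CB", "CG"],
    "GLU": ["CB", "CG"],
    "ASP": ["CB"],
    "ASN": ["CB"],
    "HIS": ["CB"],
    "HIP": ["CB"],
    "CYS": ["CB"],
}

# synthetic pseudo-residues: every atom of the residue carries the classes
PSEUDO_RESIDUES: dict[str, list[str]] = {
    "DON": ["Don"], "ACC": ["Acc"], "CAT": ["Cat"], "ANI": ["Ani"],
    "ARO": ["Aro"], "PIR": ["PiR"], "HYD": ["Hyd"], "HDA": ["HydA"],
    "DAC": ["Don", "Acc"], "DCT": ["Don", "Cat"],
    "SCF": [],  # inert scaffold
}


def residue_rules(res_name: str) -> list | None:
    """Full rule list (backbone + side chain) for a residue, or None if the
    residue is not in the template table."""
    name = res_name.upper()
    if name not in _SIDECHAIN:
        return None
    rules = list(_SIDECHAIN[name])
    if name != "PRO":
        rules.append(_BACKBONE_DON)
    rules.append(_BACKBONE_ACC)
    return rules


def hydrophobic_atoms(res_name: str) -> list[str]:
    return _HYD_ATOMS.get(res_name.upper(), [])


def class_members(label: str) -> frozenset[str]:
    """Member point-classes of a (possibly combined) feature class."""
    return frozenset(label.split("|"))


def classes_compatible(query_label: str, point_label: str) -> bool:
    """A combined class is satisfied by either of its members."""
    return bool(class_members(query_label) & class_members(point_label))
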