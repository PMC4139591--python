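"""Residue-level chemistry tables and ideal side-chain construction.

Charged-group atom names, aromatic ring definitions, aliphatic (alkyl) atom
sets, van der Waals radii and reference maximal solvent accessibilities are
collected here so that the interface detectors, the accessibility module and
the synthetic builders agree on one vocabulary.
"""

from __future__ import annotations

import numpy as np

from .structio import Atom, Residue

# --- van der Waals radii (Angstrom) -------------------------------------
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}

# --- reference maximal ASA per residue type (Gly-X-Gly, theoretical, A^2) ---
# Tien et al. 2013 theoretical values; used for relative-ASA exposure labels.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# --- formal-charge groups (atom names per residue type) ------------------
# Histidine is treated as positively charged by default (configurable at the
# detector level): its basic ring nitrogens sit in the same basic stretches
# the nuclear-localization reasoning relies on.
POSITIVE_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}
NEGATIVE_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "DA": ("OP1", "OP2"),
    "DT": ("OP1", "OP2"),
    "DG": ("OP1", "OP2"),
    "DC": ("OP1", "OP2"),
}
CTERM_NEGATIVE = "OXT"

# --- aromatic rings -------------------------------------------------------
AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (("CG", "CD1", "CD2", "NE1", "CE2"), ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
    # DNA bases: one ring definition per base (purines collapsed to the
    # fused-ring atom set; the centroid is what the stacking detector uses)
    "DA": (("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),),
    "DG": (("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),),
    "DT": (("N1", "C2", "N3", "C4", "C5", "C6"),),
    "DC": (("N1", "C2", "N3", "C4", "C5", "C6"),),
}

# --- aliphatic (alkyl) side-chain carbons --------------------------------
ALIPHATIC_ATOMS = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "CE"),
    "PRO": ("CB", "CG", "CD"),
    "LYS": ("CB", "CG", "CD", "CE"),
    "ARG": ("CB", "CG", "CD"),
    "THR": ("CG2",),
    # DNA deoxyribose carbons and the thymine methyl
    "DA": ("C1'", "C2'", "C3'", "C4'", "C5'"),
    "DT": ("C1'", "C2'", "C3'", "C4'", "C5'", "C7"),
    "DG": ("C1'", "C2'", "C3'", "C4'", "C5'"),
    "DC": ("C1'", "C2'", "C3'", "C4'", "C5'"),
}

# --- idealized straight-chain side-chain topologies ----------------------
# (atom name, element) along the CA->CB direction; terminal branched pairs
# are listed separately.  Only the types needed by charge-reversal mutation
# and by the synthetic docking peptides are covered.
_LINEAR_CHAIN = {
    "ALA": [("CB", "C")],
    "LYS": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C"), ("NZ", "N")],
    "ARG": [("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"), ("CZ", "C")],
    "GLU": [("CB", "C"), ("CG", "C"), ("CD", "C")],
    "ASP": [("CB", "C"), ("CG", "C")],
}
_BRANCH_PAIR = {
    "ARG": (("NH1", "N"), ("NH2", "N")),
    "GLU": (("OE1", "O"), ("OE2", "O")),
    "ASP": (("OD1", "O"), ("OD2", "O")),
}

SUPPORTED_MUTATION_TYPES = tuple(_LINEAR_CHAIN)

_BOND = 1.52
_BRANCH_BOND = 1.25


def ideal_side_chain(res_type: str, ca: np.ndarray, direction: np.ndarray) -> list[Atom]:
    """Idealized side chain for *res_type* grown from CA along *direction*.

    Heavy atoms are placed on a straight chain with 1.52-Angstrom spacing;
    terminal carboxylate/guanidinium pairs branch off symmetrically.  The
    resulting geometry is schematic but carries the correct atom names and
    charge-bearing termini, which is all the distance-cutoff detectors need.
    """
    res_type = res_type.upper()
    if res_type not in _LINEAR_CHAIN:
        raise ValueError(
            f"unsupported side-chain type {res_type!r}; "
            f"supported: {', '.join(sorted(_LINEAR_CHAIN))}"
        )
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    # any unit vector orthogonal to u, for the branch plane
    seed = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, seed)
    v /= np.linalg.norm(v)

    atoms: list[Atom] = []
    pos = np.asarray(ca, float)
    for name, element in _LINEAR_CHAIN[res_type]:
        pos = pos + _BOND * u
        atoms.append(Atom(name, element, pos.copy()))
    if res_type in _BRANCH_PAIR:
        tip = pos
        (n1, e1), (n2, e2) = _BRANCH_PAIR[res_type]
        half = np.radians(60.0)
        for name, element, sign in ((n1, e1, 1.0), (n2, e2, -1.0)):
            p = tip + _BRANCH_BOND * (np.cos(half) * u + sign * np.sin(half) * v)
            atoms.append(Atom(name, element, p))
    return atoms


def residue_one_letter(residue: Residue) -> str:
    return AA3_TO_1.get(residue.name.upper(), "X")
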