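"""Canonical amino-acid tables and the atom37 / atom73 coordinate layouts.

Two fixed-size per-residue layouts are used throughout the package:

* **atom37** — one slot per heavy-atom *name* occurring in any canonical
  amino acid (37 names).  A residue of a given type occupies the subset of
  slots matching its atom set; the rest are masked off.
* **atom73** — the sidechain-superposition layout: 5 shared slots
  (N, CA, C, CB, O) followed by, for each of the 20 amino acids in
  alphabetical one-letter order, its sidechain atoms beyond the shared
  five (68 slots).  Every candidate sidechain of a residue position lives
  in its own block, so all 20 rotamer states coexist until a sequence
  choice collapses them.

All orderings are frozen here; every mask elsewhere derives from these
tables.
"""

from __future__ import annotations

import numpy as np

# one-letter codes, alphabetical; index order is used everywhere
AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
AA3_TO_1 = {v: k for k, v in AA3.items()}
AA_INDEX = {aa: i for i, aa in enumerate(AA1)}

BACKBONE_ATOMS = ("N", "CA", "C", "O")
SHARED_ATOMS = ("N", "CA", "C", "CB", "O")  # shared atom73 slots

# sidechain heavy atoms beyond {N, CA, C, O, CB}, PDB standard order
SIDECHAIN_ATOMS = {
    "A": (),
    "C": ("SG",),
    "D": ("CG", "OD1", "OD2"),
    "E": ("CG", "CD", "OE1", "OE2"),
    "F": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "G": (),
    "H": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "I": ("CG1", "CG2", "CD1"),
    "K": ("CG", "CD", "CE", "NZ"),
    "L": ("CG", "CD1", "CD2"),
    "M": ("CG", "SD", "CE"),
    "N": ("CG", "OD1", "ND2"),
    "P": ("CG", "CD"),
    "Q": ("CG", "CD", "OE1", "NE2"),
    "R": ("CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "S": ("OG",),
    "T": ("OG1", "CG2"),
    "V": ("CG1", "CG2"),
    "W": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "Y": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
}

def residue_atoms(aa: str) -> tuple[str, ...]:
    """Heavy-atom names of one amino acid (glycine has no CB)."""
    if aa == "G":
        return BACKBONE_ATOMS
    return ("N", "CA", "C", "O", "CB") + SIDECHAIN_ATOMS[aa]

# ---------------------------------------------------------------- atom37
ATOM37_NAMES = (
    "N", "CA", "C", "CB", "O", "CG", "CG1", "CG2", "OG", "OG1", "SG",
    "CD", "CD1", "CD2", "ND1", "ND2", "OD1", "OD2", "SD", "CE", "CE1",
    "CE2", "CE3", "NE", "NE1", "NE2", "OE1", "OE2", "CH2", "NH1", "NH2",
    "OH", "CZ", "CZ2", "CZ3", "NZ", "OXT",
)
ATOM37_INDEX = {n: i for i, n in enumerate(ATOM37_NAMES)}

def atom37_mask(aa: str) -> np.ndarray:
    """Boolean (37,) presence mask for one amino acid."""
    m = np.zeros(37, dtype=bool)
    for name in residue_atoms(aa):
        m[ATOM37_INDEX[name]] = True
    return m

# (20, 37) mask table, row order = AA1
AA_ATOM37_MASK = np.stack([atom37_mask(aa) for aa in AA1])

# ---------------------------------------------------------------- atom73
# 5 shared slots first, then per-amino-acid sidechain blocks in
# alphabetical one-letter order.
ATOM73_NAMES: tuple[tuple[str, str], ...] = tuple(
    [("*", n) for n in SHARED_ATOMS]
    + [(aa, n) for aa in AA1 for n in SIDECHAIN_ATOMS[aa]]
)
assert len(ATOM73_NAMES) == 73

ATOM73_SHARED_SLOTS = np.arange(5)              # N, CA, C, CB, O
ATOM73_BACKBONE_SLOTS = np.array([0, 1, 2, 4])  # N, CA, C, O

_slot73 = {key: i for i, key in enumerate(ATOM73_NAMES)}

def _aa_slot_maps():
    """Per amino acid: (atom73 slots, matching atom37 slots) for collapse."""
    maps = {}
    for aa in AA1:
        s73, s37 = [], []
        shared = BACKBONE_ATOMS if aa == "G" else SHARED_ATOMS
        for name in shared:
            s73.append(_slot73[("*", name)])
            s37.append(ATOM37_INDEX[name])
        for name in SIDECHAIN_ATOMS[aa]:
            s73.append(_slot73[(aa, name)])
            s37.append(ATOM37_INDEX[name])
        maps[aa] = (np.array(s73, dtype=int), np.array(s37, dtype=int))
    return maps

AA_SLOT_MAPS = _aa_slot_maps()

def atom73_mask(aa: str, include_shared: bool = True) -> np.ndarray:
    """Boolean (73,) mask of the slots one amino acid occupies.

    With ``include_shared`` the five shared slots are set as well (for
    glycine the shared CB slot is still included: it is part of the
    superposition state and is denoised like any shared slot, only the
    collapse masks it off).
    """
    m = np.zeros(73, dtype=bool)
    if include_shared:
        m[ATOM73_SHARED_SLOTS] = True
    for name in SIDECHAIN_ATOMS[aa]:
        m[_slot73[(aa, name)]] = True
    return m

AA_ATOM73_MASK = np.stack([atom73_mask(aa) for aa in AA1])

# ------------------------------------------------------------ chi angles
# IUPAC chi-angle atom quadruples.
CHI_ATOMS = {
    "A": [],
    "C": [("N", "CA", "CB", "SG")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "G": [],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
          ("CB", "CG", "SD", "CE")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "P": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "S": [("N", "CA", "CB", "OG")],
    "T": [("N", "CA", "CB", "OG1")],
    "V": [("N", "CA", "CB", "CG1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
}

def n_chi(aa: str) -> int:
    return len(CHI_ATOMS[aa])

# ------------------------------------------------------------- tip atoms
# Sidechain "tips": the rotation-axis atoms of the final chi angle plus
# everything distal of it, backbone atoms excluded.  This reproduces the
# functional-group sets used for tip-only conditioning, e.g.
# Glu -> {CG, CD, OE1, OE2} and His -> {CB, CG, ND1, CD2, CE1, NE2}.
TIP_ATOMS = {
    "A": ("CB",),
    "C": ("CB", "SG"),
    "D": ("CB", "CG", "OD1", "OD2"),
    "E": ("CG", "CD", "OE1", "OE2"),
    "F": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "G": (),
    "H": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "I": ("CB", "CG1", "CD1"),
    "K": ("CD", "CE", "NZ"),
    "L": ("CB", "CG", "CD1", "CD2"),
    "M": ("CG", "SD", "CE"),
    "N": ("CB", "CG", "OD1", "ND2"),
    "P": ("CB", "CG", "CD"),
    "Q": ("CG", "CD", "OE1", "NE2"),
    "R": ("CD", "NE", "CZ", "NH1", "NH2"),
    "S": ("CB", "OG"),
    "T": ("CB", "OG1", "CG2"),
    "V": ("CB", "CG1", "CG2"),
    "W": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "Y": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
}

# ------------------------------------------------------------ vdW radii
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

def atom_element(name: str) -> str:
    """Element of a heavy-atom PDB name (first character suffices here)."""
    return name[0]

def validate_sequence(sequence: str) -> None:
    """Raise ValueError naming the first non-canonical position."""
    for i, aa in enumerate(sequence):
        if aa not in AA_INDEX:
            raise ValueError(
                f"non-canonical amino acid {aa!r} at position {i}"
            )
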