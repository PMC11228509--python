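"""Structure containers (atom37 and the atom73 superposition) and PDB I/O.

A :class:`ProteinStructure` is a concrete protein: one amino acid per
residue, coordinates in the fixed 37-slot heavy-atom layout with a
presence mask.  A :class:`Superposition` holds all 20 candidate
sidechains per residue at once in the 73-slot layout, along with
``sigma_last`` bookkeeping: the noise level each slot was last denoised
to, which the sampler uses to give different atoms different integration
step sizes.

``collapse`` selects one amino acid's slots per residue to produce a
concrete structure; ``update_superposition`` scatters new coordinates
back into the selected slots and leaves every other candidate untouched.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .residues import (
    AA_ATOM37_MASK,
    AA_INDEX,
    AA_SLOT_MAPS,
    ATOM37_INDEX,
    ATOM37_NAMES,
    AA3,
    AA3_TO_1,
    residue_atoms,
    validate_sequence,
)

logger = logging.getLogger(__name__)


@dataclass
class ProteinStructure:
    """One protein: sequence plus atom37-layout coordinates in Angstrom."""

    sequence: str
    coords37: np.ndarray  # (L, 37, 3) float
    mask37: np.ndarray    # (L, 37) bool
    chain_id: str = "A"

    def __post_init__(self):
        self.coords37 = np.asarray(self.coords37, dtype=float)
        self.mask37 = np.asarray(self.mask37, dtype=bool)
        L = len(self.sequence)
        if self.coords37.shape != (L, 37, 3) or self.mask37.shape != (L, 37):
            raise ValueError("coords37/mask37 shapes inconsistent with sequence")
        if not np.all(np.isfinite(self.coords37[self.mask37])):
            raise ValueError("non-finite coordinates at present atoms")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_atoms(self) -> int:
        return int(self.mask37.sum())

    def present_coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinates of present atoms, residue-major order."""
        return self.coords37[self.mask37]

    def ca_coords(self) -> np.ndarray:
        return self.coords37[:, ATOM37_INDEX["CA"], :]

    def atom_coord(self, res_index: int, atom_name: str) -> np.ndarray:
        j = ATOM37_INDEX[atom_name]
        if not self.mask37[res_index, j]:
            raise KeyError(f"atom {atom_name} absent at residue {res_index}")
        return self.coords37[res_index, j]

    def copy(self) -> "ProteinStructure":
        return ProteinStructure(
            self.sequence, self.coords37.copy(), self.mask37.copy(), self.chain_id
        )


def sequence_mask37(sequence: str) -> np.ndarray:
    """(L, 37) canonical presence mask of a sequence."""
    validate_sequence(sequence)
    idx = np.array([AA_INDEX[a] for a in sequence])
    return AA_ATOM37_MASK[idx].copy()


@dataclass
class Superposition:
    """Per-residue atom73 coordinate block with per-slot noise bookkeeping."""

    coords73: np.ndarray    # (L, 73, 3) float
    sigma_last: np.ndarray  # (L, 73) float

    def __post_init__(self):
        self.coords73 = np.asarray(self.coords73, dtype=float)
        self.sigma_last = np.asarray(self.sigma_last, dtype=float)
        if (
            self.coords73.ndim != 3
            or self.coords73.shape[1:] != (73, 3)
            or self.sigma_last.shape != self.coords73.shape[:2]
        ):
            raise ValueError("superposition arrays must be (L, 73, 3)/(L, 73)")

    @property
    def length(self) -> int:
        return self.coords73.shape[0]

    def copy(self) -> "Superposition":
        return Superposition(self.coords73.copy(), self.sigma_last.copy())


def _check_length(sp_length: int, sequence: str) -> None:
    if len(sequence) != sp_length:
        raise ValueError(
            f"sequence length {len(sequence)} != superposition length {sp_length}"
        )


def collapse(sp: Superposition, sequence: str) -> ProteinStructure:
    """Select each residue's amino-acid slots to form a concrete structure.

    Shared backbone slots are always carried over; glycine's shared CB
    slot is masked off in the output (it remains part of the
    superposition state).  Coordinates are copied unchanged.
    """
    _check_length(sp.length, sequence)
    validate_sequence(sequence)
    L = sp.length
    coords = np.zeros((L, 37, 3))
    mask = np.zeros((L, 37), dtype=bool)
    for i, aa in enumerate(sequence):
        s73, s37 = AA_SLOT_MAPS[aa]
        coords[i, s37] = sp.coords73[i, s73]
        mask[i, s37] = True
    return ProteinStructure(sequence, coords, mask)


def update_superposition(
    sp: Superposition, sequence: str, new: ProteinStructure
) -> Superposition:
    """Overwrite the slots selected by ``sequence`` from ``new``.

    All other candidate-sidechain slots are untouched.  ``new`` must carry
    exactly the canonical atom set of ``sequence``.
    """
    _check_length(sp.length, sequence)
    validate_sequence(sequence)
    if new.length != sp.length:
        raise ValueError("structure length mismatch")
    if not np.array_equal(new.mask37, sequence_mask37(sequence)):
        raise ValueError("structure mask inconsistent with sequence")
    out = sp.copy()
    for i, aa in enumerate(sequence):
        s73, s37 = AA_SLOT_MAPS[aa]
        out.coords73[i, s73] = new.coords37[i, s37]
    return out


def selected_slot_mask(sequence: str, include_shared: bool = True) -> np.ndarray:
    """(L, 73) boolean mask of the atom73 slots a sequence selects."""
    from .residues import AA_ATOM73_MASK

    validate_sequence(sequence)
    idx = np.array([AA_INDEX[a] for a in sequence])
    m = AA_ATOM73_MASK[idx].copy()
    if not include_shared:
        m[:, :5] = False
    return m


# ------------------------------------------------------ frame utilities

def center_structure(coords: np.ndarray, mask: np.ndarray | None = None):
    """Translate so the centroid of present atoms is the origin.

    Returns ``(centered, translation)`` where ``translation`` is the
    vector that was added.  All present atoms carry equal weight.
    """
    coords = np.asarray(coords, dtype=float)
    flat = coords.reshape(-1, 3)
    if mask is None:
        sel = np.ones(len(flat), dtype=bool)
    else:
        sel = np.asarray(mask, dtype=bool).reshape(-1)
    if not sel.any():
        raise ValueError("cannot center: no present atoms")
    translation = -flat[sel].mean(axis=0)
    return coords + translation, translation


def random_rotation(coords: np.ndarray, seed=None) -> np.ndarray:
    """Apply a Haar-uniform proper rotation (det +1) about the origin."""
    from scipy.spatial.transform import Rotation

    coords = np.asarray(coords, dtype=float)
    rot = Rotation.random(rng=np.random.default_rng(seed))
    return rot.apply(coords.reshape(-1, 3)).reshape(coords.shape)


# ---------------------------------------------------------------- PDB IO

def write_pdb(structure: ProteinStructure, path, b_factors=None) -> None:
    """Write ATOM records (wwPDB v3.3 columns, occupancy 1.00)."""
    lines = []
    serial = 1
    for i, aa in enumerate(structure.sequence):
        res3 = AA3[aa]
        for j in np.nonzero(structure.mask37[i])[0]:
            name = ATOM37_NAMES[j]
            x, y, z = structure.coords37[i, j]
            b = 0.0 if b_factors is None else float(b_factors[i])
            pdb_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pdb_name:<4s} {res3} "
                f"{structure.chain_id}{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pdb(path) -> ProteinStructure:
    """Read a single-model PDB file into the atom37 layout.

    Duplicated altloc atoms keep the highest occupancy (ties keep 'A');
    hetero records and atoms outside the canonical heavy-atom sets are
    skipped with a logged count; a multi-model file uses the first model
    with a warning.
    """
    residues: dict = {}
    order: list = []
    skipped = 0
    chain_id = "A"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "ENDMDL":
                warnings.warn(
                    f"{path}: multiple models; using the first", stacklevel=2
                )
                break
            if rec != "ATOM  ":
                if rec == "HETATM":
                    skipped += 1
                continue
            try:
                name = line[12:16].strip()
                altloc = line[16]
                res3 = line[17:20].strip()
                chain_id = line[21] if line[21] != " " else "A"
                resseq = int(line[22:26])
                icode = line[26]
                xyz = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
                occ_field = line[54:60].strip()
                occ = float(occ_field) if occ_field else 1.0
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: unparsable ATOM record at line {lineno}: {exc}"
                ) from exc
            aa = AA3_TO_1.get(res3)
            if aa is None or name not in ATOM37_INDEX or name == "OXT":
                skipped += 1
                continue
            if name not in residue_atoms(aa):
                skipped += 1
                continue
            key = (resseq, icode)
            if key not in residues:
                residues[key] = {"aa": aa, "atoms": {}}
                order.append(key)
            slot = residues[key]["atoms"].get(name)
            # altloc rule: keep highest occupancy, ties keep 'A'
            if slot is None or occ > slot[1] or (
                occ == slot[1] and altloc == "A" and slot[2] != "A"
            ):
                residues[key]["atoms"][name] = (xyz, occ, altloc)
    if skipped:
        logger.info("read_pdb(%s): skipped %d non-canonical atoms", path, skipped)
    if not order:
        raise ValueError(f"{path}: no canonical ATOM records found")
    L = len(order)
    seq = "".join(residues[k]["aa"] for k in order)
    coords = np.zeros((L, 37, 3))
    mask = np.zeros((L, 37), dtype=bool)
    for i, key in enumerate(order):
        for name, (xyz, _, _) in residues[key]["atoms"].items():
            j = ATOM37_INDEX[name]
            coords[i, j] = xyz
            mask[i, j] = True
    return ProteinStructure(seq, coords, mask, chain_id=chain_id)
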