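"""Sample-quality metrics: superposition-based scores (RMSD, TM-score),
diversity/novelty summaries, covalent-geometry statistics, clash
detection, and the self-consistency harness.

All structural scores are invariant to rigid rotation and translation of
either input and use a fixed residue correspondence: alpha-carbon i is
always compared with alpha-carbon i.  Structure prediction itself (the
folding oracle) happens outside this package; predictions are consumed
as residue-aligned PDB files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import dihedral, bond_angle, ideal_geometry
from .residues import ATOM37_INDEX, CHI_ATOMS, VDW_RADII, atom_element, residue_atoms
from .structure import ProteinStructure


def _ca(x) -> np.ndarray:
    if isinstance(x, ProteinStructure):
        return x.ca_coords()
    return np.asarray(x, dtype=float)


def kabsch_rmsd(coords_a, coords_b, mask=None):
    """Optimal proper-rotation superposition of B onto A.

    Returns ``(rotation, rmsd)`` where ``rotation`` is the (3, 3) proper
    rotation matrix (det +1; reflections are never used) that best maps
    centered B onto centered A, and ``rmsd`` the coordinate RMSD over the
    paired atoms after superposition.  Requires >= 3 paired atoms.
    """
    from scipy.spatial.transform import Rotation

    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if mask is not None:
        sel = np.asarray(mask, dtype=bool).reshape(-1)
        a, b = a[sel], b[sel]
    if a.shape != b.shape:
        raise ValueError("paired coordinate sets must have equal shapes")
    if len(a) < 3:
        raise ValueError("need at least 3 paired atoms")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(a, b)
    return rot.as_matrix(), float(rssd / np.sqrt(len(a)))


def tm_d0(L: int) -> float:
    """TM-score normalization length d0; floored at 0.5 for short chains."""
    if L < 16:
        return 0.5
    return max(1.24 * (L - 15) ** (1 / 3) - 1.8, 0.5)


def tm_from_distances(distances, L_target: int) -> float:
    """TM-score of given per-residue deviations: (1/L) sum 1/(1+(d/d0)^2)."""
    d = np.asarray(distances, dtype=float)
    return float(np.mean(1.0 / (1.0 + (d / tm_d0(L_target)) ** 2)))


def tm_score(coords_a, coords_b, L_target: int | None = None) -> float:
    """TM-score on a fixed residue correspondence.

    Superposes B onto A by iterative weighted Kabsch refinement (weights
    1 / (1 + (d_i/d0)^2), the score's own gradient weights) and returns
    (1/L) sum 1 / (1 + (d_i/d0)^2).  Lengths must match.
    """
    from scipy.spatial.transform import Rotation

    a, b = _ca(coords_a), _ca(coords_b)
    if a.shape != b.shape:
        raise ValueError("length mismatch between CA sets")
    L = len(a)
    if L_target is None:
        L_target = L
    d0 = tm_d0(L_target)
    w = np.ones(L)
    best = 0.0
    for _ in range(30):
        wa = a - np.average(a, axis=0, weights=w)
        wb = b - np.average(b, axis=0, weights=w)
        rot, _ = Rotation.align_vectors(wa, wb, weights=w)
        d2 = np.sum((wa - rot.apply(wb)) ** 2, axis=1)
        score = float(np.mean(1.0 / (1.0 + d2 / d0**2)))
        if score <= best + 1e-12:
            break
        best = score
        w = 1.0 / (1.0 + d2 / d0**2) ** 2
    return best


def mean_pairwise_tm(samples) -> float:
    """Mean TM-score over unordered distinct pairs of samples.

    Length-mismatched pairs are compared after truncating both to the
    shorter length (with that length as the TM normalization).
    """
    cas = [_ca(s) for s in samples]
    if len(cas) < 2:
        raise ValueError("need at least two samples")
    vals = []
    for i in range(len(cas)):
        for j in range(i + 1, len(cas)):
            L = min(len(cas[i]), len(cas[j]))
            vals.append(tm_score(cas[i][:L], cas[j][:L], L_target=L))
    return float(np.mean(vals))


def nn_tm(sample, reference_set) -> float:
    """TM-score of a sample against its nearest neighbor in a reference set."""
    refs = list(reference_set)
    if not refs:
        raise ValueError("empty reference set")
    ca = _ca(sample)
    best = 0.0
    for ref in refs:
        r = _ca(ref)
        L = min(len(ca), len(r))
        best = max(best, tm_score(ca[:L], r[:L], L_target=L))
    return best


# ------------------------------------------------------- bond geometry

@dataclass
class GeometryStats:
    bonds: pd.DataFrame    # residue, atom1, atom2, length, ideal
    angles: pd.DataFrame   # residue, atoms, value, ideal
    chis: pd.DataFrame     # residue, aa, chi, value
    bond_length_rmse: float
    n_skipped_bonds: int


def bond_geometry_stats(structure: ProteinStructure, table=None) -> GeometryStats:
    """Measure every covalent bond, bond angle and chi angle of a structure.

    Bonds with a missing atom are skipped and counted.  The bond-length
    RMSE is the root-mean-square deviation of each measured bond length
    from its ideal reference value (peptide C-N bonds included).
    """
    if table is None:
        table = ideal_geometry()
    brec, arec, crec = [], [], []
    skipped = 0
    for i, aa in enumerate(structure.sequence):
        present = {
            n for n in residue_atoms(aa) if structure.mask37[i, ATOM37_INDEX[n]]
        }
        coord = lambda n: structure.coords37[i, ATOM37_INDEX[n]]  # noqa: E731
        for a1, a2 in table.bonds[aa]:
            if a1 in present and a2 in present:
                brec.append(
                    (i, a1, a2, float(np.linalg.norm(coord(a1) - coord(a2))),
                     table.ideal_length(aa, a1, a2))
                )
            else:
                skipped += 1
        for (a, b, c), ideal in table.bond_angles[aa].items():
            if {a, b, c} <= present:
                arec.append((i, f"{a}-{b}-{c}", bond_angle(coord(a), coord(b), coord(c)), ideal))
        for k, quad in enumerate(CHI_ATOMS[aa]):
            if set(quad) <= present:
                crec.append((i, aa, k + 1, dihedral(*(coord(n) for n in quad))))
    # peptide bonds between consecutive residues
    nC, nN = ATOM37_INDEX["C"], ATOM37_INDEX["N"]
    for i in range(structure.length - 1):
        if structure.mask37[i, nC] and structure.mask37[i + 1, nN]:
            d = float(
                np.linalg.norm(structure.coords37[i, nC] - structure.coords37[i + 1, nN])
            )
            brec.append((i, "C", "N+1", d, table.peptide_bond_length))
        else:
            skipped += 1
    bonds = pd.DataFrame(brec, columns=["residue", "atom1", "atom2", "length", "ideal"])
    angles = pd.DataFrame(arec, columns=["residue", "atoms", "value", "ideal"])
    chis = pd.DataFrame(crec, columns=["residue", "aa", "chi", "value"])
    rmse = float(np.sqrt(np.mean((bonds["length"] - bonds["ideal"]) ** 2))) if len(bonds) else float("nan")
    return GeometryStats(bonds, angles, chis, rmse, skipped)


# ----------------------------------------------------------- clashes

def _bond_steps(table, aa1, aa2, adjacency_cache):
    """Adjacency of a residue pair (aa1 followed by aa2, peptide-bonded)."""
    adj = {}
    for tag, aa in (("a", aa1), ("b", aa2)):
        for a1, a2 in table.bonds[aa]:
            adj.setdefault((tag, a1), set()).add((tag, a2))
            adj.setdefault((tag, a2), set()).add((tag, a1))
    adj.setdefault(("a", "C"), set()).add(("b", "N"))
    adj.setdefault(("b", "N"), set()).add(("a", "C"))
    return adj


def _bfs_within(adj, src, max_depth):
    out = {src: 0}
    frontier = [src]
    for depth in range(1, max_depth + 1):
        nxt = []
        for node in frontier:
            for nb in adj.get(node, ()):
                if nb not in out:
                    out[nb] = depth
                    nxt.append(nb)
        frontier = nxt
    return out


def clash_fraction(structure: ProteinStructure, overlap_factor: float = 0.63) -> float:
    """Percentage of residues with at least one non-bonded heavy-atom clash.

    A clash is a pair of atoms at least 4 covalent bonds apart (any pair
    from non-adjacent residues qualifies) whose distance is below
    ``overlap_factor`` times the sum of their van der Waals radii.
    """
    from scipy.spatial import cKDTree

    if overlap_factor <= 0:
        return 0.0
    table = ideal_geometry()
    atoms = []  # (res_idx, name, radius, coord)
    for i, aa in enumerate(structure.sequence):
        for n in residue_atoms(aa):
            j = ATOM37_INDEX[n]
            if structure.mask37[i, j]:
                atoms.append((i, n, VDW_RADII[atom_element(n)], structure.coords37[i, j]))
    if not atoms:
        return 0.0
    coords = np.stack([a[3] for a in atoms])
    tree = cKDTree(coords)
    max_r = overlap_factor * 2 * max(VDW_RADII.values())
    flagged: set[int] = set()
    pair_cache: dict = {}
    for p, q in tree.query_pairs(max_r):
        ri, ni, radi, ci = atoms[p]
        rj, nj, radj, cj = atoms[q]
        d = float(np.linalg.norm(ci - cj))
        if d >= overlap_factor * (radi + radj):
            continue
        if abs(ri - rj) > 1:
            flagged.update((ri, rj))
            continue
        # same or adjacent residue: check the covalent path length
        if ri == rj:
            key = (structure.sequence[ri], None)
            if key not in pair_cache:
                pair_cache[key] = _bond_steps(table, structure.sequence[ri], "G", None)
            adj = pair_cache[key]
            src, dst = ("a", ni), ("a", nj)
        else:
            aa1, aa2 = structure.sequence[min(ri, rj)], structure.sequence[max(ri, rj)]
            key = (aa1, aa2)
            if key not in pair_cache:
                pair_cache[key] = _bond_steps(table, aa1, aa2, None)
            adj = pair_cache[key]
            src = ("a" if ri < rj else "b", ni)
            dst = ("a" if rj < ri else "b", nj)
        dists = _bfs_within(adj, src, 3)
        if dst not in dists:  # >= 4 bonds apart
            flagged.update((ri, rj))
    return 100.0 * len(flagged) / structure.length


# ---------------------------------------------------- self-consistency

def self_consistency(sample, predicted) -> dict:
    """scRMSD / scTM between a sample and the structure predicted from its
    designed sequence, plus the standard success flags
    (scRMSD < 2 A, scTM > 0.5)."""
    ca_s, ca_p = _ca(sample), _ca(predicted)
    if ca_s.shape != ca_p.shape:
        raise ValueError("sample and prediction must be residue-aligned")
    _, rmsd = kabsch_rmsd(ca_s, ca_p)
    tm = tm_score(ca_s, ca_p)
    return {
        "scRMSD": rmsd,
        "scTM": tm,
        "rmsd_success": bool(rmsd < 2.0),
        "tm_success": bool(tm > 0.5),
    }
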