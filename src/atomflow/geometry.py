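"""Ideal covalent geometry and internal-coordinate residue building.

The ideal reference geometry has two sources, merged into one table so
that fixture generation and geometry metrics agree exactly:

* backbone bond lengths / angles are fixed Engh-Huber-style constants
  (frozen below), used by the helix builder;
* sidechain geometry (bond lengths, angles, default conformation) comes
  from the idealized chemical-component templates bundled with biotite.

Chi angles follow the IUPAC atom quadruples in :mod:`atomflow.residues`,
reported in (-180, 180] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .residues import AA1, AA3, CHI_ATOMS, n_chi, residue_atoms

# frozen backbone reference values (lengths in Angstrom, angles in degrees)
BACKBONE_BOND_LENGTHS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "O"): 1.231,
    ("C", "N"): 1.329,  # peptide bond (inter-residue)
}
BACKBONE_BOND_ANGLES = {
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "O"): 120.8,
    ("CA", "C", "N"): 116.2,
    ("C", "N", "CA"): 121.7,
}

# ------------------------------------------------------- vector helpers

def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    u, v = np.asarray(a) - b, np.asarray(c) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC convention, (-180, 180]."""
    b0 = np.asarray(p1) - p0
    b1 = np.asarray(p2) - p1
    b2 = np.asarray(p3) - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |c-d|=bond, angle(b,c,d)=angle, dihedral(a,b,c,d)=torsion.

    Standard internal-coordinate (NeRF) construction; angles in degrees.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _rotate_about_axis(points, origin, axis, angle_deg):
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    return rot.apply(np.asarray(points, dtype=float) - origin) + origin


# --------------------------------------------------- ideal geometry table

@dataclass(frozen=True)
class IdealGeometryTable:
    """Per-amino-acid ideal internal coordinates.

    ``template[aa]`` maps heavy-atom name -> ideal 3D coordinate (the
    residue in its default conformation); ``bonds[aa]`` lists intra-residue
    heavy-atom bonds; ``bond_lengths[aa]`` and ``bond_angles[aa]`` hold the
    ideal values implied by the template (backbone entries overridden by
    the frozen constants); ``chi_atoms`` are the IUPAC chi quadruples.
    ``peptide_bond_length`` is the inter-residue C-N ideal value.
    """

    template: dict = field(default_factory=dict)
    bonds: dict = field(default_factory=dict)
    bond_lengths: dict = field(default_factory=dict)
    bond_angles: dict = field(default_factory=dict)
    chi_atoms: dict = field(default_factory=lambda: dict(CHI_ATOMS))
    peptide_bond_length: float = BACKBONE_BOND_LENGTHS[("C", "N")]

    def ideal_length(self, aa: str, a1: str, a2: str) -> float:
        key = (a1, a2) if (a1, a2) in self.bond_lengths[aa] else (a2, a1)
        return self.bond_lengths[aa][key]

    def adjacency(self, aa: str) -> dict:
        adj: dict[str, set] = {n: set() for n in residue_atoms(aa)}
        for a1, a2 in self.bonds[aa]:
            adj[a1].add(a2)
            adj[a2].add(a1)
        return adj

    def downstream_atoms(self, aa: str, a2: str, a3: str) -> list[str]:
        """Atoms on the a3 side of bond a2-a3 (a3 excluded), via BFS."""
        adj = self.adjacency(aa)
        seen = {a2, a3}
        stack = [n for n in adj[a3] if n != a2]
        out = []
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            out.append(n)
            stack.extend(adj[n] - seen)
        return out


def _heavy_template(aa: str):
    import biotite.structure.info as info

    arr = info.residue(AA3[aa])
    names = set(residue_atoms(aa))
    coords = {}
    for atom in arr:
        if atom.atom_name in names:
            coords[atom.atom_name] = np.array(atom.coord, dtype=float)
    missing = names - set(coords)
    if missing:  # pragma: no cover - CCD templates are complete
        raise RuntimeError(f"CCD template for {aa} missing atoms {missing}")

    def _snap(atom, ref, length, carry=()):
        u = coords[atom] - coords[ref]
        new = coords[ref] + length * u / np.linalg.norm(u)
        shift = new - coords[atom]
        coords[atom] = new
        for other in carry:
            coords[other] = coords[other] + shift

    # normalize backbone bond lengths to the frozen reference constants
    # (directions, and hence bond angles, are untouched)
    _snap("C", "CA", BACKBONE_BOND_LENGTHS[("CA", "C")], carry=("O",))
    _snap("O", "C", BACKBONE_BOND_LENGTHS[("C", "O")])
    _snap("N", "CA", BACKBONE_BOND_LENGTHS[("N", "CA")])
    return coords


@lru_cache(maxsize=1)
def ideal_geometry() -> IdealGeometryTable:
    """Build (once) the merged ideal-geometry table for all 20 amino acids."""
    import biotite.structure.info as info

    template, bonds, lengths, angles = {}, {}, {}, {}
    for aa in AA1:
        coords = _heavy_template(aa)
        names = set(coords)
        blist = []
        for (a1, a2) in info.bonds_in_residue(AA3[aa]):
            if a1 in names and a2 in names:
                blist.append(tuple(sorted((a1, a2))))
        blist = sorted(set(blist))
        ltab = {}
        for a1, a2 in blist:
            if (a1, a2) in (("CA", "N"), ("C", "CA"), ("C", "O")):
                pair = (a2, a1) if (a2, a1) in BACKBONE_BOND_LENGTHS else (a1, a2)
                ltab[(a1, a2)] = BACKBONE_BOND_LENGTHS[pair]
            else:
                ltab[(a1, a2)] = float(np.linalg.norm(coords[a1] - coords[a2]))
        adj: dict[str, set] = {n: set() for n in names}
        for a1, a2 in blist:
            adj[a1].add(a2)
            adj[a2].add(a1)
        atab = {}
        for b in sorted(names):
            nbrs = sorted(adj[b])
            for i in range(len(nbrs)):
                for j in range(i + 1, len(nbrs)):
                    a, c = nbrs[i], nbrs[j]
                    key = (a, b, c)
                    if key in BACKBONE_BOND_ANGLES:
                        atab[key] = BACKBONE_BOND_ANGLES[key]
                    elif (c, b, a) in BACKBONE_BOND_ANGLES:
                        atab[key] = BACKBONE_BOND_ANGLES[(c, b, a)]
                    else:
                        atab[key] = bond_angle(coords[a], coords[b], coords[c])
        template[aa] = coords
        bonds[aa] = blist
        lengths[aa] = ltab
        angles[aa] = atab
    return IdealGeometryTable(
        template=template, bonds=bonds, bond_lengths=lengths, bond_angles=angles
    )


# ------------------------------------------------------ residue building

def measure_chis(aa: str, coords: dict) -> np.ndarray:
    """Chi angles (degrees) of a residue given name -> coordinate mapping."""
    return np.array(
        [dihedral(*(coords[n] for n in quad)) for quad in CHI_ATOMS[aa]]
    )


def build_residue_from_chis(
    aa: str,
    chis,
    backbone: np.ndarray | None = None,
) -> dict:
    """Build one all-atom residue at the given chi angles.

    Starts from the ideal template, optionally superposes its N/CA/C onto
    ``backbone`` (a (3, 3) array of N, CA, C positions), then rotates each
    chi's distal atoms about the chi bond to hit the requested values.
    Returns a name -> coordinate dict.  Raises on a chi-count mismatch.
    """
    chis = np.atleast_1d(np.asarray(chis, dtype=float))
    if chis.size != n_chi(aa):
        raise ValueError(
            f"{aa} takes {n_chi(aa)} chi angles, got {chis.size}"
        )
    table = ideal_geometry()
    coords = {k: v.copy() for k, v in table.template[aa].items()}
    if backbone is not None:
        from scipy.spatial.transform import Rotation

        backbone = np.asarray(backbone, dtype=float)
        src = np.stack([coords[n] for n in ("N", "CA", "C")])
        src_c, dst_c = src.mean(axis=0), backbone.mean(axis=0)
        rot, _ = Rotation.align_vectors(backbone - dst_c, src - src_c)
        for k in coords:
            coords[k] = rot.apply(coords[k] - src_c) + dst_c
        # snap CA exactly onto the target frame so bonds to CA keep their
        # ideal lengths despite the (small) backbone-triangle misfit
        shift = backbone[1] - coords["CA"]
        for k in coords:
            coords[k] = coords[k] + shift
    for i, quad in enumerate(CHI_ATOMS[aa]):
        a1, a2, a3, a4 = quad
        current = dihedral(coords[a1], coords[a2], coords[a3], coords[a4])
        delta = chis[i] - current
        moving = table.downstream_atoms(aa, a2, a3)
        pts = np.stack([coords[n] for n in moving])
        # rotating the distal side about the a2->a3 axis by -delta raises
        # the measured dihedral by +delta under the sign convention above
        pts = _rotate_about_axis(pts, coords[a2], coords[a3] - coords[a2], -delta)
        for n, p in zip(moving, pts):
            coords[n] = p
    return coords
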