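"""Superposition collapse/update, frame utilities and PDB round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atomflow.residues import AA1, ATOM37_INDEX, residue_atoms
from atomflow.structure import (
    ProteinStructure,
    Superposition,
    center_structure,
    collapse,
    random_rotation,
    read_pdb,
    sequence_mask37,
    update_superposition,
    write_pdb,
)

SEQS = st.text(alphabet=AA1, min_size=2, max_size=6)


def random_sp(L, seed=0):
    rng = np.random.default_rng(seed)
    return Superposition(rng.standard_normal((L, 73, 3)), np.ones((L, 73)))


def test_collapse_histidine_has_ten_atoms():
    sp = random_sp(1)
    s = collapse(sp, "H")
    assert s.n_atoms == 10
    present = {n for n in residue_atoms("H") if s.mask37[0, ATOM37_INDEX[n]]}
    assert present == set(residue_atoms("H"))


def test_collapse_glycine_masks_cb():
    s = collapse(random_sp(1), "G")
    assert s.n_atoms == 4
    assert not s.mask37[0, ATOM37_INDEX["CB"]]


def test_collapse_errors():
    sp = random_sp(3)
    with pytest.raises(ValueError, match="length"):
        collapse(sp, "AA")
    with pytest.raises(ValueError, match="position 1"):
        collapse(sp, "AXA")


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seq=SEQS, seed=st.integers(0, 100))
def test_collapse_update_roundtrip(seq, seed):
    """update(collapse(sp, s), s) leaves the superposition unchanged."""
    sp = random_sp(len(seq), seed)
    out = update_superposition(sp, seq, collapse(sp, seq))
    np.testing.assert_array_equal(out.coords73, sp.coords73)


def test_update_glycine_touches_backbone_only():
    sp = random_sp(2, 1)
    new = collapse(sp, "GG")
    new.coords37[:, [0, 1, 2, 4]] += 1.0
    out = update_superposition(sp, "GG", new)
    changed = np.any(out.coords73 != sp.coords73, axis=2)
    assert set(np.nonzero(changed)[1]) == {0, 1, 2, 4}


def test_update_mask_inconsistency_errors():
    sp = random_sp(2)
    new = collapse(sp, "AA")
    with pytest.raises(ValueError, match="mask"):
        update_superposition(sp, "VV", new)


def test_disjoint_updates_commute_on_sidechains():
    """Residue-wise different amino acids write to disjoint sidechain slots."""
    sp = random_sp(3, 2)
    rng = np.random.default_rng(3)
    s_a, s_b = "LKE", "VQH"
    new_a, new_b = collapse(sp, s_a), collapse(sp, s_b)
    new_a.coords37 += rng.standard_normal(new_a.coords37.shape)
    new_b.coords37 += rng.standard_normal(new_b.coords37.shape)
    ab = update_superposition(update_superposition(sp, s_a, new_a), s_b, new_b)
    ba = update_superposition(update_superposition(sp, s_b, new_b), s_a, new_a)
    # sidechain slots (everything beyond the 5 shared) commute exactly
    np.testing.assert_array_equal(ab.coords73[:, 5:], ba.coords73[:, 5:])


def test_center_structure_examples(rng):
    coords = rng.standard_normal((7, 3))
    centered, t = center_structure(coords)
    assert np.linalg.norm(centered.mean(axis=0)) < 1e-9
    again, t2 = center_structure(centered)
    assert np.linalg.norm(t2) < 1e-9  # idempotent
    shifted, t3 = center_structure(centered + np.array([5.0, -3.0, 2.0]))
    np.testing.assert_allclose(t3, [-5.0, 3.0, -2.0], atol=1e-9)
    with pytest.raises(ValueError):
        center_structure(coords, mask=np.zeros(7, dtype=bool))


def test_center_structure_uses_only_present_atoms(rng):
    coords = rng.standard_normal((4, 3))
    mask = np.array([True, True, True, False])
    centered, _ = center_structure(coords, mask)
    assert np.linalg.norm(centered[:3].mean(axis=0)) < 1e-9


def test_random_rotation_is_proper_isometry(rng):
    from scipy.spatial.distance import pdist

    coords = rng.standard_normal((10, 3))
    rotated = random_rotation(coords, seed=5)
    np.testing.assert_allclose(pdist(coords), pdist(rotated), atol=1e-9)
    # recover the matrix and check det +1
    from atomflow.metrics import kabsch_rmsd

    R, _ = kabsch_rmsd(rotated - rotated.mean(0), coords - coords.mean(0))
    assert np.linalg.det(R) > 0.999


def test_random_rotation_haar_mean_is_zero():
    """The Haar average of rotation matrices is the zero matrix."""
    basis = np.eye(3)
    acc = np.zeros((3, 3))
    n = 4000
    for seed in range(n):
        acc += random_rotation(basis, seed=seed)
    # entries are means of bounded variables; 3 sigma ~ 3*0.58/sqrt(n)
    assert np.abs(acc / n).max() < 0.03


def test_pdb_roundtrip(tmp_path, mixed_helix):
    path = tmp_path / "helix.pdb"
    write_pdb(mixed_helix, path)
    back = read_pdb(path)
    assert back.sequence == mixed_helix.sequence
    np.testing.assert_array_equal(back.mask37, mixed_helix.mask37)
    np.testing.assert_allclose(
        back.coords37[back.mask37], mixed_helix.coords37[mixed_helix.mask37],
        atol=1e-3,
    )


def test_pdb_backbone_only_mask(tmp_path):
    seq = "AAA"
    coords = np.zeros((3, 37, 3))
    coords[:, [0, 1, 2, 4]] = np.random.default_rng(0).standard_normal((3, 4, 3))
    mask = np.zeros((3, 37), dtype=bool)
    mask[:, [0, 1, 2, 4]] = True
    s = ProteinStructure(seq, coords, mask)
    path = tmp_path / "bb.pdb"
    write_pdb(s, path)
    back = read_pdb(path)
    for i in range(3):
        names = {n for n in residue_atoms("A") if back.mask37[i, ATOM37_INDEX[n]]}
        assert names == {"N", "CA", "C", "O"}


def test_pdb_altloc_keeps_highest_occupancy(tmp_path):
    lines = [
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA AALA A   1       1.000   0.000   0.000  0.40  0.00           C",
        "ATOM      3  CA BALA A   1       2.000   0.000   0.000  0.60  0.00           C",
        "ATOM      4  C   ALA A   1       3.000   0.000   0.000  1.00  0.00           C",
        "ATOM      5  O   ALA A   1       4.000   0.000   0.000  1.00  0.00           O",
        "END",
    ]
    p = tmp_path / "alt.pdb"
    p.write_text("\n".join(lines) + "\n")
    s = read_pdb(p)
    assert s.coords37[0, ATOM37_INDEX["CA"], 0] == pytest.approx(2.0)  # occ 0.60 wins


def test_pdb_altloc_tie_prefers_a(tmp_path):
    lines = [
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N",
        "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.50  0.00           C",
        "ATOM      3  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C",
        "ATOM      4  C   ALA A   1       3.000   0.000   0.000  1.00  0.00           C",
        "ATOM      5  O   ALA A   1       4.000   0.000   0.000  1.00  0.00           O",
    ]
    p = tmp_path / "alt.pdb"
    p.write_text("\n".join(lines) + "\n")
    s = read_pdb(p)
    assert s.coords37[0, ATOM37_INDEX["CA"], 0] == pytest.approx(1.0)


def test_pdb_unparsable_record_reports_line(tmp_path):
    p = tmp_path / "bad.pdb"
    p.write_text(
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00\n"
        "ATOM      2  CA  ALA A   1       xxxxx   0.000   0.000  1.00  0.00\n"
    )
    with pytest.raises(ValueError, match="line 2"):
        read_pdb(p)


def test_pdb_multimodel_warns_and_uses_first(tmp_path, helix12):
    p = tmp_path / "m.pdb"
    write_pdb(helix12, p)
    text = p.read_text().replace("END\n", "ENDMDL\nMODEL 2\nEND\n")
    p.write_text(text)
    with pytest.warns(UserWarning, match="first"):
        s = read_pdb(p)
    assert s.length == helix12.length


def test_mask_matches_sequence_atom_sets(mixed_helix):
    np.testing.assert_array_equal(
        mixed_helix.mask37, sequence_mask37(mixed_helix.sequence)
    )
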