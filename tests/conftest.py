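import numpy as np
import pytest

from atomflow import NoiseSchedule
from atomflow.synthetic import make_ideal_helix


def stretch_all_bonds(aa: str, delta: float):
    """Build one residue with every covalent bond lengthened by ``delta``.

    Walks the (acyclic) bond tree away from N, translating each distal
    subtree along its bond direction, so each bond changes by exactly
    ``delta`` and all others are carried rigidly.  Returns a
    ProteinStructure of the single residue.
    """
    from atomflow.geometry import ideal_geometry
    from atomflow.residues import ATOM37_INDEX
    from atomflow.structure import ProteinStructure, sequence_mask37

    table = ideal_geometry()
    coords = {k: v.copy() for k, v in table.template[aa].items()}
    for a1, a2 in sorted(table.bonds[aa]):
        side_of_a1 = set(table.downstream_atoms(aa, a2, a1)) | {a1}
        parent, child = (a1, a2) if "N" in side_of_a1 else (a2, a1)
        u = coords[child] - coords[parent]
        u /= np.linalg.norm(u)
        for n in set([child] + table.downstream_atoms(aa, parent, child)):
            coords[n] = coords[n] + delta * u
    c37 = np.zeros((1, 37, 3))
    for n, xyz in coords.items():
        c37[0, ATOM37_INDEX[n]] = xyz
    return ProteinStructure(aa, c37, sequence_mask37(aa))


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_helix(12)


@pytest.fixture(scope="session")
def mixed_helix():
    # small, clash-light residues at default rotamers
    return make_ideal_helix(12, sequence="ASGVTLASGVTL")


@pytest.fixture(scope="session")
def unit_schedule():
    """sigma_data = 1 toy schedule used by the Gaussian-oracle tests."""
    return NoiseSchedule(sigma_min=0.01, sigma_max=80.0, n_steps=100, sigma_data=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
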