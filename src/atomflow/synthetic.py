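"""Deterministic synthetic fixtures: ideal helices, single residues built
from chi angles, and Gaussian "protein" toys with known denoising oracles.

These generators make every stage of the pipeline testable without any
external structure downloads: the helix has every bond at its ideal
reference value (so geometry metrics have an exact zero point), and the
Gaussian toys have closed-form optimal denoisers (so samplers and
likelihoods can be checked against analytic results).
"""

from __future__ import annotations

import numpy as np

from .geometry import (
    BACKBONE_BOND_ANGLES,
    BACKBONE_BOND_LENGTHS,
    build_residue_from_chis,
    ideal_geometry,
    measure_chis,
    place_atom,
)
from .residues import ATOM37_INDEX, n_chi, residue_atoms
from .structure import ProteinStructure, Superposition, sequence_mask37

ALPHA_PHI = -57.0
ALPHA_PSI = -47.0
OMEGA = 180.0


def default_chis(aa: str) -> np.ndarray:
    """Default rotamer: the chi angles of the ideal template conformation."""
    if n_chi(aa) == 0:
        return np.zeros(0)
    return measure_chis(aa, ideal_geometry().template[aa])


def make_ideal_helix(
    n_residues: int,
    sequence: str | None = None,
    phi: float = ALPHA_PHI,
    psi: float = ALPHA_PSI,
) -> ProteinStructure:
    """Build an idealized alpha-helix with all-atom sidechains.

    The backbone is grown by internal coordinates with every bond length
    and angle at its reference value and torsions (phi, psi, omega=180);
    sidechains are ideal templates at their default rotamers, rigidly
    attached to each residue's N/CA/C frame.  Poly-alanine by default.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    if sequence is None:
        sequence = "A" * n_residues
    if len(sequence) != n_residues:
        raise ValueError("sequence length mismatch")

    bl, ba = BACKBONE_BOND_LENGTHS, BACKBONE_BOND_ANGLES
    N = [np.zeros(3)]
    CA = [np.array([bl[("N", "CA")], 0.0, 0.0])]
    ang = np.radians(180.0 - ba[("N", "CA", "C")])
    C = [CA[0] + bl[("CA", "C")] * np.array([np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_residues):
        N.append(place_atom(N[-1], CA[-1], C[-1], bl[("C", "N")], ba[("CA", "C", "N")], psi))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i], bl[("N", "CA")], ba[("C", "N", "CA")], OMEGA))
        C.append(place_atom(C[i - 1], N[i], CA[i], bl[("CA", "C")], ba[("N", "CA", "C")], phi))
    O = [
        place_atom(N[i], CA[i], C[i], bl[("C", "O")], ba[("CA", "C", "O")], psi + 180.0)
        for i in range(n_residues)
    ]

    coords = np.zeros((n_residues, 37, 3))
    mask = sequence_mask37(sequence)
    for i, aa in enumerate(sequence):
        coords[i, ATOM37_INDEX["N"]] = N[i]
        coords[i, ATOM37_INDEX["CA"]] = CA[i]
        coords[i, ATOM37_INDEX["C"]] = C[i]
        coords[i, ATOM37_INDEX["O"]] = O[i]
        if aa != "G":
            built = build_residue_from_chis(
                aa, default_chis(aa), backbone=np.stack([N[i], CA[i], C[i]])
            )
            for name in residue_atoms(aa):
                if name not in ("N", "CA", "C", "O"):
                    coords[i, ATOM37_INDEX[name]] = built[name]
    return ProteinStructure(sequence, coords, mask)


def make_gaussian_protein_toy(
    length: int,
    means=None,
    variances=1.0,
    seed: int = 0,
    n_samples: int = 1,
    center: bool = False,
):
    """Independent-Gaussian atom73 toy with its exact posterior-mean oracle.

    Each of the 73 slots' coordinates is drawn independently from
    N(mean, variance) (``means`` broadcastable to (length, 73, 3),
    ``variances`` to (length, 73, 1)).  Returns ``(samples, oracle)``
    where ``samples`` has shape (n_samples, length, 73, 3) and ``oracle``
    is the closed-form optimal denoiser of this distribution, so
    sampler/likelihood marginal-recovery tests have an exact reference.
    """
    from .denoise import GaussianOracle

    if np.any(np.asarray(variances) <= 0):
        raise ValueError("variances must be positive")
    rng = np.random.default_rng(seed)
    mu = np.zeros((length, 73, 3)) + (0.0 if means is None else np.asarray(means))
    var = np.broadcast_to(np.asarray(variances, dtype=float), (length, 73))[..., None]
    samples = mu + np.sqrt(var) * rng.standard_normal((n_samples, length, 73, 3))
    if center:
        samples = samples - samples.reshape(n_samples, -1, 3).mean(axis=1)[:, None, None, :]
    oracle = GaussianOracle(mean=mu, var=var)
    return samples, oracle


def toy_superposition(sample: np.ndarray, sigma: float = 0.0) -> Superposition:
    """Wrap one (length, 73, 3) toy draw as a Superposition."""
    sample = np.asarray(sample, dtype=float)
    return Superposition(sample, np.full(sample.shape[:2], float(sigma)))
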