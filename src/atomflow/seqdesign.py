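"""Structure-conditioned sequence prediction for codesign sampling.

Any callable ``(x0_structure, sigma, prev=..., rng=...) -> (probs, seq)``
can drive the all-atom sampler.  The bundled
:class:`ToySequencePredictor` scores each amino acid at each position by
rigidly fitting that amino acid's ideal all-atom template to the
residue's denoised channel coordinates, turning the fit errors into a
softmax whose temperature grows with the noise level (high noise -> a
near-uniform, exploratory sequence; low noise -> a committed one), with
optional self-conditioning on the previous step's sequence estimate.

It is a desk-scale stand-in for a learned inverse-folding network and
deliberately sees the full 37-channel coordinate block rather than a
sequence-derived atom subset, mirroring the anti-leakage convention of
noising all 37 channels.
"""

from __future__ import annotations

import logging

import numpy as np

from .geometry import ideal_geometry
from .residues import AA1, ATOM37_INDEX, residue_atoms
from .structure import ProteinStructure

logger = logging.getLogger(__name__)


def _kabsch_sse(template: np.ndarray, observed: np.ndarray) -> float:
    """Sum of squared residuals after optimal proper-rotation superposition."""
    from scipy.spatial.transform import Rotation

    t = template - template.mean(axis=0)
    o = observed - observed.mean(axis=0)
    _, rssd = Rotation.align_vectors(o, t)
    return float(rssd**2)


class ToySequencePredictor:
    """Template-fit amino-acid scoring with a noise-scaled softmax.

    Per residue and candidate amino acid the score is
    (SSE + miss_penalty * n_missing + extra_penalty * n_unexplained) / n,
    where SSE is the squared-residual template fit over channels shared
    by template and residue, ``n_missing`` counts template atoms with no
    present channel and ``n_unexplained`` counts present sidechain
    channels the template does not use.  Logits are -score / T(sigma)
    with T = t0 * (1 + (sigma / sigma_ref)^2).
    """

    def __init__(
        self,
        t0: float = 0.01,
        sigma_ref: float = 1.0,
        miss_penalty: float = 1.0,
        extra_penalty: float = 1.0,
        self_cond_weight: float = 0.5,
    ):
        self.t0 = t0
        self.sigma_ref = sigma_ref
        self.miss_penalty = miss_penalty
        self.extra_penalty = extra_penalty
        self.self_cond_weight = self_cond_weight
        table = ideal_geometry()
        self._templates = {}
        for aa in AA1:
            names = residue_atoms(aa)
            slots = np.array([ATOM37_INDEX[n] for n in names])
            coords = np.stack([table.template[aa][n] for n in names])
            self._templates[aa] = (slots, coords)

    def _residue_scores(self, coords37: np.ndarray, mask37) -> np.ndarray:
        present = (
            np.ones(37, dtype=bool) if mask37 is None else np.asarray(mask37, bool)
        )
        scores = np.empty(len(AA1))
        backbone = {ATOM37_INDEX[n] for n in ("N", "CA", "C", "O")}
        for k, aa in enumerate(AA1):
            slots, tmpl = self._templates[aa]
            have = present[slots]
            matched = slots[have]
            n_missing = int((~have).sum())
            in_tmpl = np.zeros(37, dtype=bool)
            in_tmpl[slots] = True
            n_extra = int(
                sum(1 for j in np.nonzero(present)[0] if not in_tmpl[j] and j not in backbone)
            )
            sse = (
                _kabsch_sse(tmpl[have], coords37[matched]) if have.sum() >= 3 else 0.0
            )
            n = len(matched) + n_missing + n_extra
            scores[k] = (
                sse + self.miss_penalty * n_missing + self.extra_penalty * n_extra
            ) / max(n, 1)
        return scores

    def __call__(self, structure, sigma: float, prev: str | None = None, rng=None):
        if isinstance(structure, ProteinStructure):
            coords, mask = structure.coords37, structure.mask37
        else:
            coords = np.asarray(structure, dtype=float)
            mask = None
        L = coords.shape[0]
        T = self.t0 * (1.0 + (float(sigma) / self.sigma_ref) ** 2)
        probs = np.empty((L, 20))
        for i in range(L):
            s = self._residue_scores(coords[i], None if mask is None else mask[i])
            logits = -s / T
            logits -= logits.max()
            p = np.exp(logits)
            probs[i] = p / p.sum()
        if prev is not None:
            if len(prev) != L:
                raise ValueError("previous sequence length mismatch")
            w = self.self_cond_weight
            onehot = np.zeros((L, 20))
            for i, aa in enumerate(prev):
                onehot[i, AA1.index(aa)] = 1.0
            probs = (1 - w) * probs + w * onehot
        seq = "".join(AA1[j] for j in probs.argmax(axis=1))
        return probs, seq


def final_step_designer_hook(
    internal_sequence: str, external_sequence: str | None = None
) -> str:
    """Terminal-step sequence swap.

    If an externally designed sequence is supplied it replaces the
    internal estimate verbatim (lengths must match); otherwise the
    internal argmax sequence is kept.  Either way the choice is logged.
    """
    if external_sequence is None:
        logger.info("final step: keeping internal sequence estimate")
        return internal_sequence
    if len(external_sequence) != len(internal_sequence):
        raise ValueError(
            f"external sequence length {len(external_sequence)} != "
            f"structure length {len(internal_sequence)}"
        )
    logger.info("final step: replacing internal sequence with external design")
    return external_sequence


# ------------------------------------------------------------- FASTA IO

def read_fasta(path) -> dict:
    """Read sequences as an {id: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seq_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s), id=str(name), description="") for name, s in sequences.items()
    ]
    seq_write(records, str(path), "fasta")
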