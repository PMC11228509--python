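"""Stochastic probability-flow ODE sampling, plain and with the atom73
sidechain superposition.

The plain sampler (:func:`sample_ode`) integrates dx = -sigma * score
dsigma with the Euler method on a warped noise ladder, optionally
injecting stochasticity at each step ("churn": temporarily raising the
noise level and adding matching Gaussian noise) and scaling the
denoising step by ``step_scale`` (an inverse temperature: scores scaled
by beta sample the beta-tempered density).

The all-atom sampler (:func:`sample_allatom`) runs the same integrator
on a :class:`~atomflow.structure.Superposition`.  Each iteration
collapses the current noisy superposition with the current sequence
estimate, denoises that concrete structure, re-predicts the sequence
from the denoised estimate, re-collapses with the *new* sequence, and
takes per-atom Euler steps: the shared backbone slots step every
iteration while each candidate sidechain steps only when its amino acid
is selected, integrating from the level it was last denoised to
(``sigma_last``) — so rarely selected sidechains take larger
delta-sigma steps.  A step's order is: denoise, predict, churn the
stepped slots, Euler; so the network always sees coordinates at their
tracked noise levels.

All randomness flows through :class:`SeededNoise`, which derives an
independent stream per (step, purpose) from one integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .diffusion import NoiseSchedule, discretize_sigmas
from .structure import (
    ProteinStructure,
    Superposition,
    collapse,
    selected_slot_mask,
    sequence_mask37,
    update_superposition,
)

_TAGS = {"init": 0, "churn": 1, "sequence": 2, "guidance": 3, "stage2": 4}


class SeededNoise:
    """Deterministic per-(step, purpose) Gaussian noise streams."""

    def __init__(self, seed: int):
        self.seed = int(seed) % (2**31)

    def _rng(self, step: int, tag: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, step + 2, _TAGS[tag]])
        )

    def draw(self, step: int, tag: str, shape) -> np.ndarray:
        return self._rng(step, tag).standard_normal(shape)

    def generator(self, step: int, tag: str) -> np.random.Generator:
        return self._rng(step, tag)


@dataclass(frozen=True)
class Stage2Config:
    """Second-stage (rotamer-repacking) settings."""

    start_sigma: float = 2.0
    n_steps: int = 25
    backbone_flex: float = 0.0  # fraction of start_sigma applied to the backbone

    def __post_init__(self):
        if self.start_sigma <= 0 or self.n_steps < 2 or self.backbone_flex < 0:
            raise ValueError("invalid stage-2 settings")


@dataclass(frozen=True)
class SamplerConfig:
    """All tunable sampling knobs."""

    schedule: NoiseSchedule = field(default_factory=NoiseSchedule)
    s_churn: float = 0.0
    step_scale: float = 1.0
    seed: int = 0
    stage2: Stage2Config | None = None
    substeps: int = 1  # per-atom Euler sub-steps per iteration (superposition)

    def __post_init__(self):
        if self.s_churn < 0:
            raise ValueError("s_churn must be non-negative")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be positive")
        if self.substeps < 1:
            raise ValueError("substeps must be at least 1")

    def gamma(self) -> float:
        if self.s_churn == 0:
            return 0.0
        return min(self.s_churn / self.schedule.n_steps, math.sqrt(2) - 1)


@dataclass
class TrajectoryState:
    """Evolving state of the all-atom sampling loop."""

    sp_t: Superposition
    sp_0: Superposition
    seq_hat: str
    sigma_now: float
    step: int


# ------------------------------------------------------- step primitives

def euler_denoise_step(x, x0_hat, sigma_from, sigma_to, step_scale=1.0):
    """One Euler step of the probability-flow ODE, per atom.

    x + (sigma_to - sigma_from) * step_scale * (x - x0_hat) / sigma_from,
    where ``sigma_from`` may be a per-atom array (broadcast against x).
    """
    x = np.asarray(x, dtype=float)
    x0_hat = np.asarray(x0_hat, dtype=float)
    s_from = np.asarray(sigma_from, dtype=float)
    s_to = np.asarray(sigma_to, dtype=float)
    if np.any(s_from <= s_to) or np.any(s_to < 0):
        raise ValueError("need sigma_from > sigma_to >= 0")
    if s_from.ndim and s_from.shape == x.shape[: s_from.ndim] and s_from.ndim < x.ndim:
        s_from = s_from.reshape(s_from.shape + (1,) * (x.ndim - s_from.ndim))
    if s_to.ndim and s_to.shape == x.shape[: s_to.ndim] and s_to.ndim < x.ndim:
        s_to = s_to.reshape(s_to.shape + (1,) * (x.ndim - s_to.ndim))
    return x + (s_to - s_from) * step_scale * (x - x0_hat) / s_from


def churn(x, sigma, gamma, seed=None, rng=None, z=None):
    """Raise the noise level by a factor (1 + gamma) with matching noise.

    Returns (x_hat, sigma_hat) with sigma_hat = sigma * (1 + gamma) and
    x_hat = x + sqrt(sigma_hat^2 - sigma^2) * z; a no-op at gamma = 0.
    The marginal N(x0, sigma^2) is mapped onto N(x0, sigma_hat^2).
    """
    x = np.asarray(x, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    sigma_hat = sigma * (1.0 + gamma)
    if gamma == 0:
        return x.copy(), sigma_hat
    if z is None:
        if rng is None:
            rng = np.random.default_rng(seed)
        z = rng.standard_normal(x.shape)
    s = sigma
    if s.ndim and s.shape == x.shape[: s.ndim] and s.ndim < x.ndim:
        s = s.reshape(s.shape + (1,) * (x.ndim - s.ndim))
    return x + np.sqrt((s * (1.0 + gamma)) ** 2 - s**2) * z, sigma_hat


# ----------------------------------------------------------- plain ODE

def sample_ode(
    denoiser,
    shape,
    config: SamplerConfig,
    noise: SeededNoise | None = None,
    guidance_fn=None,
    pre_fn=None,
    callback=None,
):
    """Integrate the probability-flow ODE from the Gaussian prior.

    ``shape`` may carry leading batch dimensions; the denoiser is applied
    to the whole array at the scalar trajectory noise level.
    ``pre_fn(x, sigma, step) -> x`` transforms the noisy state before the
    denoise (replacement guidance hooks in here);
    ``guidance_fn(x, x0_hat, sigma, step) -> adjusted x0_hat`` hooks in
    reconstruction guidance; ``callback(step, sigma, x, x0_hat)``
    observes the trajectory.  Step order: denoise, churn, Euler.
    """
    if noise is None:
        noise = SeededNoise(config.seed)
    sched = config.schedule
    sigmas = discretize_sigmas(sched)
    x = sched.sigma_max * noise.draw(-1, "init", shape)
    gamma = config.gamma()
    for i in range(len(sigmas) - 1):
        s, s_next = float(sigmas[i]), float(sigmas[i + 1])
        if pre_fn is not None:
            x = pre_fn(x, s, i)
        x0_hat = denoiser(x, s)
        if guidance_fn is not None:
            x0_hat = guidance_fn(x, x0_hat, s, i)
        if gamma > 0:
            x, s_hat = churn(x, s, gamma, z=noise.draw(i, "churn", shape))
        else:
            s_hat = s
        x = euler_denoise_step(x, x0_hat, s_hat, s_next, config.step_scale)
        if callback is not None:
            callback(i, s_hat, x, x0_hat)
    return x


# ------------------------------------------------------ backbone model

BACKBONE_SLOTS37 = np.array([0, 1, 2, 4])  # N, CA, C, O in atom37


def sample_backbone(denoiser, length: int, config: SamplerConfig) -> ProteinStructure:
    """Backbone-only generation: the 4 shared N, CA, C, O slots, no sequence."""
    if length < 2:
        raise ValueError("length must be at least 2")
    x = sample_ode(denoiser, (length, 4, 3), config)
    coords = np.zeros((length, 37, 3))
    coords[:, BACKBONE_SLOTS37] = x
    seq = "G" * length
    return ProteinStructure(seq, coords, sequence_mask37(seq))


def sample_backbone_ensemble(
    denoiser, length: int, config: SamplerConfig, n_samples: int
) -> np.ndarray:
    """Many independent backbone trajectories at once.

    Returns (n_samples, length, 4, 3) terminal coordinates; each batch
    element follows its own trajectory (independent noise), vectorized
    through the denoiser for marginal-recovery statistics.
    """
    return sample_ode(denoiser, (n_samples, length, 4, 3), config)


# ------------------------------------------------------ all-atom model

def _per_atom_sigma(structure_mask_slots, sigma_last, slots73_per_res):
    return None


def _collapse_sigma(sp: Superposition, sequence: str) -> np.ndarray:
    """Per-present-atom sigma_last of the collapsed atom set, (L, 37)-shaped."""
    from .residues import AA_SLOT_MAPS

    L = sp.length
    out = np.zeros((L, 37))
    for i, aa in enumerate(sequence):
        s73, s37 = AA_SLOT_MAPS[aa]
        out[i, s37] = sp.sigma_last[i, s73]
    return out


def _scatter_structure(sp: Superposition, sequence: str, coords37: np.ndarray) -> None:
    """In-place update of the slots selected by sequence from (L,37,3) coords."""
    from .residues import AA_SLOT_MAPS

    for i, aa in enumerate(sequence):
        s73, s37 = AA_SLOT_MAPS[aa]
        sp.coords73[i, s73] = coords37[i, s37]


def _call_predictor(predictor, structure, sigma, prev, rng):
    try:
        return predictor(structure, sigma, prev=prev, rng=rng)
    except TypeError:
        return predictor(structure, sigma, prev=prev)


def sample_allatom(
    denoiser,
    seq_predictor,
    length: int,
    config: SamplerConfig,
    noise: SeededNoise | None = None,
    external_sequence: str | None = None,
    init_sequence: str | None = None,
    state_callback=None,
):
    """All-atom structure/sequence codesign with a sidechain superposition.

    Returns ``(structure, sequence, trajectory_log)``.  The predictor is
    any callable ``(x0_structure, sigma, prev=..., rng=...) ->
    (probs, sequence)``.  If ``external_sequence`` is given it replaces
    the internal estimate at the terminal step (the designer-swap hook).
    """
    from .seqdesign import final_step_designer_hook

    if length < 2:
        raise ValueError("length must be at least 2")
    if noise is None:
        noise = SeededNoise(config.seed)
    sched = config.schedule
    sigmas = discretize_sigmas(sched)
    gamma = config.gamma()
    per_atom_ok = getattr(denoiser, "supports_per_atom_sigma", False)

    sp_t = Superposition(
        sched.sigma_max * noise.draw(-1, "init", (length, 73, 3)),
        np.full((length, 73), sched.sigma_max),
    )
    sp_0 = Superposition(np.zeros((length, 73, 3)), np.zeros((length, 73)))

    # bootstrap sequence estimate from a first denoise of the raw noise
    seq_hat = init_sequence if init_sequence is not None else "A" * length
    x_net = collapse(sp_t, seq_hat)
    sig_net = _collapse_sigma(sp_t, seq_hat) if per_atom_ok else float(sigmas[0])
    x0_net = np.asarray(denoiser(x_net.coords37, sig_net), dtype=float)
    _scatter_structure(sp_0, seq_hat, x0_net)
    x0_struct = ProteinStructure(seq_hat, x0_net, sequence_mask37(seq_hat))
    _, seq_hat = _call_predictor(
        seq_predictor, x0_struct, float(sigmas[0]), None, noise.generator(-1, "sequence")
    )

    log = []
    for i in range(len(sigmas) - 1):
        s, s_next = float(sigmas[i]), float(sigmas[i + 1])
        # 1. network input: collapse the noisy superposition at the current sequence
        x_net = collapse(sp_t, seq_hat)
        sig_net = _collapse_sigma(sp_t, seq_hat) if per_atom_ok else s
        x0_net = np.asarray(denoiser(x_net.coords37, sig_net), dtype=float)
        # 2. fold the fresh estimate into X0 and re-predict the sequence
        _scatter_structure(sp_0, seq_hat, x0_net)
        x0_struct = ProteinStructure(seq_hat, x0_net, sequence_mask37(seq_hat))
        _, seq_new = _call_predictor(
            seq_predictor, x0_struct, s, seq_hat, noise.generator(i, "sequence")
        )
        # 3. re-collapse both superpositions with the NEW sequence
        stepped = selected_slot_mask(seq_new)  # (L, 73) incl. shared slots
        x_step = sp_t.coords73
        sig_from = sp_t.sigma_last
        # 4. churn the stepped slots, then per-atom Euler to the target level
        if gamma > 0:
            z = noise.draw(i, "churn", (length, 73, 3))
            churned, _ = churn(x_step, sig_from, gamma, z=z)
            x_step = np.where(stepped[..., None], churned, x_step)
            sig_hat = np.where(stepped, sig_from * (1.0 + gamma), sig_from)
        else:
            sig_hat = sig_from
        # per-atom integration, optionally split into sub-steps with the
        # denoiser re-evaluated at the intermediate (per-atom) noise levels;
        # targets interpolate linearly in the rho-warped space per atom
        rho = sched.rho
        sig_cur = sig_hat
        for k in range(config.substeps):
            if k > 0:
                x_net_k = collapse(
                    Superposition(x_step, sig_cur), seq_new
                )
                sig_net_k = (
                    _collapse_sigma(Superposition(x_step, sig_cur), seq_new)
                    if per_atom_ok
                    else max(
                        s_next,
                        (s ** (1 / rho) + (k / config.substeps) * (s_next ** (1 / rho) - s ** (1 / rho))) ** rho,
                    )
                )
                x0_k = np.asarray(denoiser(x_net_k.coords37, sig_net_k), dtype=float)
                _scatter_structure(sp_0, seq_new, x0_k)
            frac = (k + 1) / config.substeps
            sig_to = (
                sig_hat ** (1 / rho)
                + frac * (s_next ** (1 / rho) - sig_hat ** (1 / rho))
            ) ** rho
            new_x = euler_denoise_step(
                x_step,
                sp_0.coords73,
                np.where(stepped, sig_cur, sig_to + 1.0),  # dummy level off-mask
                np.where(stepped, sig_to, sig_to),
                config.step_scale,
            )
            x_step = np.where(stepped[..., None], new_x, x_step)
            sig_cur = np.where(stepped, sig_to, sig_cur)
        sp_t.coords73 = x_step
        sp_t.sigma_last = np.where(stepped, s_next, sp_t.sigma_last)
        log.append(
            {
                "step": i,
                "sigma": s,
                "sigma_next": s_next,
                "sequence": seq_new,
                "n_seq_changed": sum(a != b for a, b in zip(seq_hat, seq_new)),
                "n_stepped_slots": int(stepped.sum()),
            }
        )
        seq_hat = seq_new
        if state_callback is not None:
            state_callback(TrajectoryState(sp_t, sp_0, seq_hat, s_next, i))

    seq_final = final_step_designer_hook(seq_hat, external_sequence)
    # slots the final sequence selects that were never denoised to zero fall
    # back to their X0 estimate (a single terminal Euler step to sigma = 0)
    coords73 = np.where(
        (sp_t.sigma_last > 0)[..., None], sp_0.coords73, sp_t.coords73
    )
    out = collapse(Superposition(coords73, np.zeros((length, 73))), seq_final)
    return out, seq_final, log


# ---------------------------------------------------------- stage 2

def sample_stage2_repack(
    denoiser,
    fixed: ProteinStructure,
    config: SamplerConfig,
    noise: SeededNoise | None = None,
) -> ProteinStructure:
    """Re-sample sidechains conditioned on a fixed backbone and sequence.

    The sidechain atoms (including CB) of the given sequence are re-noised
    to ``stage2.start_sigma`` and denoised down the ladder; backbone atoms
    are conditioned by replacement and stay bit-identical unless
    ``stage2.backbone_flex`` > 0, in which case they are noised to
    ``backbone_flex * start_sigma`` and take denoising steps as well.
    No sequence predictor is involved.
    """
    stage2 = config.stage2 if config.stage2 is not None else Stage2Config()
    if noise is None:
        noise = SeededNoise(config.seed)
    seq = fixed.sequence
    L = fixed.length
    bb_mask = sequence_mask37(seq).copy()
    bb_mask[:, :] = False
    bb_mask[:, BACKBONE_SLOTS37] = True
    if not np.all(fixed.mask37[:, BACKBONE_SLOTS37]):
        raise ValueError("fixed structure is missing backbone atoms")
    if not np.all(np.isfinite(fixed.coords37[fixed.mask37])):
        raise ValueError("fixed structure has non-finite coordinates")

    sp = Superposition(np.zeros((L, 73, 3)), np.zeros((L, 73)))
    sp = update_superposition(sp, seq, fixed)
    selected = selected_slot_mask(seq)
    shared_bb = np.zeros(73, dtype=bool)
    shared_bb[[0, 1, 2, 4]] = True  # N, CA, C, O shared slots
    side = selected & ~shared_bb[None, :]  # sidechain slots incl. shared CB
    flex = stage2.backbone_flex
    stepped = side | (shared_bb[None, :] & (flex > 0)) & selected

    start = np.where(side, stage2.start_sigma, 0.0)
    if flex > 0:
        start = np.where(shared_bb[None, :] & selected, flex * stage2.start_sigma, start)
    z = noise.draw(-1, "stage2", (L, 73, 3))
    sp.coords73 = sp.coords73 + start[..., None] * z
    sp.sigma_last = start

    sub = config.schedule.with_(
        sigma_max=stage2.start_sigma,
        sigma_min=min(config.schedule.sigma_min, stage2.start_sigma / 100),
        n_steps=stage2.n_steps,
    )
    sigmas = discretize_sigmas(sub)
    gamma = SamplerConfig(
        schedule=sub, s_churn=config.s_churn, step_scale=config.step_scale
    ).gamma()
    per_atom_ok = getattr(denoiser, "supports_per_atom_sigma", False)
    for i in range(len(sigmas) - 1):
        s, s_next = float(sigmas[i]), float(sigmas[i + 1])
        active = stepped & (sp.sigma_last > s_next)
        if not active.any():
            continue
        x_net = collapse(sp, seq)
        sig_net = _collapse_sigma(sp, seq) if per_atom_ok else s
        x0_net = np.asarray(denoiser(x_net.coords37, sig_net), dtype=float)
        sp0 = Superposition(sp.coords73.copy(), np.zeros((L, 73)))
        _scatter_structure(sp0, seq, x0_net)
        x = sp.coords73
        sig_from = sp.sigma_last
        if gamma > 0:
            zc = noise.draw(i, "churn", (L, 73, 3))
            churned, _ = churn(x, sig_from, gamma, z=zc)
            x = np.where(active[..., None], churned, x)
            sig_hat = np.where(active, sig_from * (1.0 + gamma), sig_from)
        else:
            sig_hat = sig_from
        new_x = euler_denoise_step(
            x, sp0.coords73, np.where(active, sig_hat, s_next + 1.0), s_next,
            config.step_scale,
        )
        sp.coords73 = np.where(active[..., None], new_x, sp.coords73)
        sp.sigma_last = np.where(active, s_next, sp.sigma_last)

    out = collapse(sp, seq)
    if flex == 0:
        out.coords37[:, BACKBONE_SLOTS37] = fixed.coords37[:, BACKBONE_SLOTS37]
    return out
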