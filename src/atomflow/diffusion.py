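"""The sigma(t) = t variance-exploding diffusion process.

Time and noise level are identified throughout: the forward process adds
isotropic Gaussian noise of scale sigma to centered coordinates, with
marginals p_sigma(x) = p_0 * N(0, sigma^2 I), and sampling integrates the
probability-flow ODE dx = -sigma * score dsigma.  The score is obtained
from any denoiser D via score = (D(x, sigma) - x) / sigma^2.

The training side provides the warped sampling discretization, the
log-normal training-noise distribution, the preconditioning scalars
(c_skip, c_out, c_in, c_noise, lambda) and the weighted denoising
score-matching loss.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class NoiseSchedule:
    """Noise-process parameters.

    sigma_min / sigma_max bound the sampled noise range (Angstrom); rho
    warps the sampling discretization toward small sigma; sigma_data is
    the characteristic data scale used by preconditioning; p_mean / p_std
    parameterize the log-normal training-noise distribution (p_mean
    defaults to ln(sigma_data) - 1.2).
    """

    sigma_min: float = 0.01
    sigma_max: float = 80.0
    rho: float = 7.0
    n_steps: int = 100
    sigma_data: float = 1.0
    p_mean: float | None = None
    p_std: float = 1.2

    def __post_init__(self):
        if not (0 < self.sigma_min < self.sigma_max):
            raise ValueError("need 0 < sigma_min < sigma_max")
        if self.rho <= 0 or self.sigma_data <= 0 or self.p_std <= 0:
            raise ValueError("rho, sigma_data and p_std must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        if self.p_mean is None:
            object.__setattr__(self, "p_mean", float(np.log(self.sigma_data)) - 1.2)

    def with_(self, **kwargs) -> "NoiseSchedule":
        return replace(self, **kwargs)


def estimate_sigma_data(coord_sets) -> float:
    """Root-mean-square coordinate magnitude after centering, over a dataset."""
    sq, n = 0.0, 0
    for coords in coord_sets:
        flat = np.asarray(coords, dtype=float).reshape(-1, 3)
        flat = flat - flat.mean(axis=0)
        sq += float((flat**2).sum())
        n += flat.size
    if n == 0:
        raise ValueError("empty dataset")
    return float(np.sqrt(sq / n))


def marginal_sample(x0, sigma, seed=None, rng=None):
    """Draw x0 + sigma * z with z standard normal per coordinate."""
    x0 = np.asarray(x0, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    if np.all(sigma == 0):
        return x0.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    return x0 + sigma * rng.standard_normal(x0.shape)


def score_from_denoiser(x, sigma, denoised):
    """score = (D(x, sigma) - x) / sigma^2; undefined at sigma = 0."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("score undefined at sigma <= 0")
    return (np.asarray(denoised, dtype=float) - np.asarray(x, dtype=float)) / sigma**2


def discretize_sigmas(schedule: NoiseSchedule) -> np.ndarray:
    """Strictly decreasing noise ladder with a terminal zero.

    sigma_i = (sigma_max^(1/rho) + i/(n-1) * (sigma_min^(1/rho) -
    sigma_max^(1/rho)))^rho for i = 0..n-1, then 0 appended: n+1 values.
    """
    n, rho = schedule.n_steps, schedule.rho
    lo, hi = schedule.sigma_min ** (1 / rho), schedule.sigma_max ** (1 / rho)
    i = np.arange(n) / (n - 1)
    sigmas = (hi + i * (lo - hi)) ** rho
    return np.append(sigmas, 0.0)


def sample_training_sigma(schedule: NoiseSchedule, seed=None, rng=None, size=None):
    """Log-normal training noise: exp(p_mean + p_std * z)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=size)
    return np.exp(schedule.p_mean + schedule.p_std * z)


def preconditioning(sigma, sigma_data):
    """EDM preconditioning scalars (c_skip, c_out, c_in, c_noise, loss_weight).

    The denoiser is assembled as D(x, sigma) = c_skip * x +
    c_out * F(c_in * x, c_noise) for any raw network F, and the DSM loss
    weight is lambda(sigma) = 1 / c_out^2.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("preconditioning requires sigma > 0")
    sd2 = sigma_data**2
    tot = sigma**2 + sd2
    c_skip = sd2 / tot
    c_out = sigma * sigma_data / np.sqrt(tot)
    c_in = 1.0 / np.sqrt(tot)
    c_noise = np.log(sigma) / 4.0
    loss_weight = 1.0 / c_out**2
    return c_skip, c_out, c_in, c_noise, loss_weight


def dsm_loss(denoised, x0, sigma, sigma_data, mask=None):
    """Weighted denoising score-matching loss, mean over present coordinates.

    lambda(sigma) ||D - x0||^2 with lambda = 1/c_out^2; with the optimal
    (posterior-mean) denoiser the expected per-coordinate value is 1 at
    every noise level.
    """
    denoised = np.asarray(denoised, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if denoised.shape != x0.shape:
        raise ValueError("shape mismatch between denoised and x0")
    _, _, _, _, w = preconditioning(sigma, sigma_data)
    w = np.asarray(w, dtype=float)
    diff2 = (denoised - x0) ** 2
    if w.ndim and w.shape == diff2.shape[: w.ndim] and w.ndim < diff2.ndim:
        w = w.reshape(w.shape + (1,) * (diff2.ndim - w.ndim))
    sq = w * diff2
    if mask is not None:
        m = np.broadcast_to(
            np.asarray(mask, dtype=bool)[..., None]
            if np.asarray(mask).shape == sq.shape[:-1]
            else np.asarray(mask, dtype=bool),
            sq.shape,
        )
        if not m.any():
            raise ValueError("empty mask")
        return float(sq[m].mean())
    return float(sq.mean())
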