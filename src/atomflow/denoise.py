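"""Denoisers: the contract, closed-form oracles, and a trainable toy model.

A *denoiser* is any callable ``D(x, sigma) -> xhat0`` estimating clean
coordinates from noisy ones.  ``x`` may carry arbitrary leading batch
dimensions; ``sigma`` may be a scalar or (for denoisers advertising
``supports_per_atom_sigma``) an array broadcastable against ``x``, so
different atoms can sit at different noise levels.  The optimal denoiser
is the posterior mean E[x0 | x], which is available in closed form for
Gaussian and Gaussian-mixture data; those oracles make every stage of
the sampling machinery testable against analytic results.

Denoisers may additionally expose ``jacobian(x, sigma)`` (the derivative
of the flattened output w.r.t. the flattened input) which guidance and
likelihood use for exact gradients/divergences when available.

The :class:`ToyDenoiser` is a deliberately tiny multilayer perceptron
wrapped in EDM preconditioning.  Its purpose is to exercise the training
objective and the sampler end to end on a CPU; the contract accepts any
stronger network in its place.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .diffusion import (
    NoiseSchedule,
    dsm_loss,
    preconditioning,
    sample_training_sigma,
)

CHECKPOINT_VERSION = 1


def _sigma_expand(sigma, x):
    """Broadcast sigma against x, adding a coordinate axis for per-atom shapes."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim and sigma.shape == x.shape[: sigma.ndim] and sigma.ndim < x.ndim:
        sigma = sigma.reshape(sigma.shape + (1,) * (x.ndim - sigma.ndim))
    return sigma


@dataclass
class GaussianOracle:
    """Posterior-mean denoiser for i.i.d. Gaussian data N(mean, var) per coordinate."""

    mean: float | np.ndarray = 0.0
    var: float | np.ndarray = 1.0
    supports_per_atom_sigma: bool = True
    jacobian_is_constant: bool = True  # linear in x at fixed sigma

    def __post_init__(self):
        if np.any(np.asarray(self.var) <= 0):
            raise ValueError("var must be positive")

    def __call__(self, x, sigma):
        x = np.asarray(x, dtype=float)
        s2 = _sigma_expand(sigma, x) ** 2
        return (self.var * x + s2 * self.mean) / (self.var + s2)

    def jacobian(self, x, sigma):
        if np.ndim(self.var):
            raise NotImplementedError("jacobian only for scalar-variance oracles")
        x = np.asarray(x, dtype=float)
        a = self.var / (self.var + float(np.asarray(sigma)) ** 2)
        return a * np.eye(x.size)

    def divergence(self, x, sigma):
        x = np.asarray(x, dtype=float)
        s2 = _sigma_expand(sigma, x) ** 2
        return float(np.sum(self.var / (self.var + s2) * np.ones_like(x)))


@dataclass
class MultivariateGaussianOracle:
    """Posterior-mean denoiser for jointly Gaussian data N(mean, cov) over a
    flattened coordinate vector; used for correlated-coordinate toys."""

    mean: np.ndarray
    cov: np.ndarray
    supports_per_atom_sigma: bool = True
    jacobian_is_constant: bool = True  # linear in x at fixed sigma

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("cov shape inconsistent with mean")

    def _gain(self, sigma):
        d = self.mean.size
        s2 = np.asarray(sigma, dtype=float) ** 2 * np.ones(d)
        return self.cov @ np.linalg.inv(self.cov + np.diag(s2))

    def __call__(self, x, sigma):
        x = np.asarray(x, dtype=float)
        A = self._gain(sigma)
        return self.mean + (x - self.mean) @ A.T

    def jacobian(self, x, sigma):
        return self._gain(sigma)

    def divergence(self, x, sigma):
        return float(np.trace(self._gain(sigma)))


@dataclass
class GMMOracle:
    """Posterior-mean denoiser for an isotropic Gaussian-mixture density.

    Components k have weight w_k, mean mu_k (a length-D vector or scalar)
    and per-coordinate variance v_k.  The estimate is the responsibility-
    weighted combination of per-component Gaussian posterior means, with
    responsibilities proportional to w_k N(x; mu_k, (v_k + sigma^2) I).
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    supports_per_atom_sigma: bool = True

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.weights.size == 0:
            raise ValueError("empty mixture")
        self.weights = self.weights / self.weights.sum()
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        if self.means.ndim == 1:
            self.means = self.means[:, None]
        self.variances = np.atleast_1d(np.asarray(self.variances, dtype=float))
        if np.any(self.variances <= 0):
            raise ValueError("component variances must be positive")

    def _responsibilities(self, x, sigma):
        # x: (..., D); returns (..., K) log-normalized responsibilities
        s2 = _sigma_expand(sigma, x) ** 2
        log_r = []
        for k in range(self.weights.size):
            tot = self.variances[k] + s2
            ll = -0.5 * np.sum(
                (x - self.means[k]) ** 2 / tot + np.log(2 * np.pi * tot), axis=-1
            )
            log_r.append(np.log(self.weights[k]) + ll)
        log_r = np.stack(log_r, axis=-1)
        log_r -= log_r.max(axis=-1, keepdims=True)
        r = np.exp(log_r)
        return r / r.sum(axis=-1, keepdims=True)

    def __call__(self, x, sigma):
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 0
        x = np.atleast_1d(x)
        s2 = _sigma_expand(sigma, x) ** 2
        r = self._responsibilities(x, sigma)
        out = np.zeros_like(x)
        for k in range(self.weights.size):
            post = (self.variances[k] * x + s2 * self.means[k]) / (
                self.variances[k] + s2
            )
            out += r[..., k : k + 1] * post
        return out[0] if squeeze else out

    def log_density(self, x, sigma):
        """Analytic log-density of the sigma-smoothed mixture (for tests)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        s2 = _sigma_expand(sigma, x) ** 2
        comps = []
        for k in range(self.weights.size):
            tot = self.variances[k] + s2
            ll = -0.5 * np.sum(
                (x - self.means[k]) ** 2 / tot + np.log(2 * np.pi * tot), axis=-1
            )
            comps.append(np.log(self.weights[k]) + ll)
        from scipy.special import logsumexp

        return logsumexp(np.stack(comps, axis=-1), axis=-1)


def gaussian_oracle(x, sigma, mean=0.0, var=1.0):
    """Functional form of :class:`GaussianOracle`."""
    return GaussianOracle(mean=mean, var=var)(x, sigma)


def gmm_oracle(x, sigma, weights, means, variances):
    """Functional form of :class:`GMMOracle`."""
    return GMMOracle(weights, means, variances)(x, sigma)


# ------------------------------------------------------------ toy model

def _mlp_forward(coefs, intercepts, X):
    h = X
    for W, b in zip(coefs[:-1], intercepts[:-1]):
        h = np.maximum(h @ W + b, 0.0)
    return h @ coefs[-1] + intercepts[-1]


@dataclass
class ToyDenoiser:
    """A tiny preconditioned MLP denoiser over flattened coordinates.

    The raw network F sees (c_in * x, c_noise) and the denoiser output is
    assembled as c_skip * x + c_out * F(...).  ``sigma`` may be scalar or
    per-example; a single noise level per example is assumed (the network
    input path of the sampler).
    """

    dim: int
    sigma_data: float
    coefs: list = field(default_factory=list)
    intercepts: list = field(default_factory=list)
    train_loss: float | None = None
    holdout_loss: float | None = None
    supports_per_atom_sigma: bool = False

    def raw(self, x_scaled, c_noise):
        X = np.concatenate([x_scaled, c_noise], axis=-1)
        flat = X.reshape(-1, self.dim + 1)
        out = _mlp_forward(self.coefs, self.intercepts, flat)
        return out.reshape(x_scaled.shape)

    def __call__(self, x, sigma):
        x = np.asarray(x, dtype=float)
        squeeze = x.ndim == 1
        xb = x[None] if squeeze else x
        sig = np.broadcast_to(np.asarray(sigma, dtype=float), xb.shape[:-1])
        c_skip, c_out, c_in, c_noise, _ = preconditioning(sig, self.sigma_data)
        F = self.raw(c_in[..., None] * xb, c_noise[..., None])
        out = c_skip[..., None] * xb + c_out[..., None] * F
        return out[0] if squeeze else out


def train_toy_denoiser(
    dataset,
    schedule: NoiseSchedule,
    seed: int = 0,
    n_iters: int = 300,
    hidden=(64, 64),
    draws_per_example: int = 64,
    rotation_augment: bool = False,
    holdout_fraction: float = 0.1,
) -> ToyDenoiser:
    """Fit a :class:`ToyDenoiser` by denoising score matching.

    ``dataset`` is an (N, D) array of flattened, centered coordinate
    examples (for atom37 fixtures the caller flattens all 37 channels so
    every channel is noised, not only present atoms).  Each example is
    corrupted ``draws_per_example`` times at log-normal noise levels; the
    preconditioned regression targets (x0 - c_skip x) / c_out are fit
    with an Adam-trained MLP for ``n_iters`` epochs.  Deterministic under
    ``seed``.  Raises if the training diverges or if the held-out DSM
    loss fails to drop below the untrained (F = 0) baseline.
    """
    from sklearn.neural_network import MLPRegressor

    data = np.asarray(dataset, dtype=float)
    if data.ndim != 2 or len(data) == 0:
        raise ValueError("dataset must be a nonempty (N, D) array")
    n, dim = data.shape
    rng = np.random.default_rng(seed)

    reps = np.repeat(data, draws_per_example, axis=0)
    if rotation_augment:
        if dim % 3:
            raise ValueError("rotation augmentation requires 3D coordinate examples")
        from scipy.spatial.transform import Rotation

        rots = Rotation.random(len(reps), rng=rng)
        reps = np.stack(
            [r.apply(x.reshape(-1, 3)).reshape(-1) for r, x in zip(rots, reps)]
        )
    sig = sample_training_sigma(schedule, rng=rng, size=len(reps))
    noisy = reps + sig[:, None] * rng.standard_normal(reps.shape)
    c_skip, c_out, c_in, c_noise, _ = preconditioning(sig, schedule.sigma_data)
    X = np.concatenate([c_in[:, None] * noisy, c_noise[:, None]], axis=1)
    Y = (reps - c_skip[:, None] * noisy) / c_out[:, None]

    n_hold = max(1, int(holdout_fraction * len(X)))
    perm = rng.permutation(len(X))
    hold, fit = perm[:n_hold], perm[n_hold:]

    mlp = MLPRegressor(
        hidden_layer_sizes=tuple(hidden),
        activation="relu",
        solver="adam",
        max_iter=n_iters,
        random_state=int(np.random.default_rng(seed + 1).integers(2**31 - 1)),
        tol=0.0,
        n_iter_no_change=n_iters,
        learning_rate_init=3e-3,
    )
    import warnings as _warnings

    with _warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        _warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(X[fit], Y[fit])
    if not all(np.all(np.isfinite(c)) for c in mlp.coefs_):
        raise FloatingPointError("toy denoiser training diverged (non-finite weights)")

    den = ToyDenoiser(
        dim=dim,
        sigma_data=schedule.sigma_data,
        coefs=[np.asarray(W, dtype=float) for W in mlp.coefs_],
        intercepts=[np.asarray(b, dtype=float) for b in mlp.intercepts_],
    )
    den_hold = den(noisy[hold], sig[hold])
    base_hold = c_skip[hold, None] * noisy[hold]
    loss_after = dsm_loss(den_hold, reps[hold], sig[hold], schedule.sigma_data)
    loss_before = dsm_loss(base_hold, reps[hold], sig[hold], schedule.sigma_data)
    if not np.isfinite(loss_after):
        raise FloatingPointError("toy denoiser training diverged (non-finite loss)")
    if loss_after >= loss_before:
        raise RuntimeError(
            f"held-out DSM loss did not improve ({loss_after:.3f} >= {loss_before:.3f})"
        )
    den.train_loss = float(mlp.loss_)
    den.holdout_loss = float(loss_after)
    return den


# ------------------------------------------------------ checkpoint I/O

def save_checkpoint(denoiser: ToyDenoiser, path) -> None:
    """Write a JSON checkpoint with a version field."""
    payload = {
        "version": CHECKPOINT_VERSION,
        "dim": denoiser.dim,
        "sigma_data": denoiser.sigma_data,
        "coefs": [W.tolist() for W in denoiser.coefs],
        "intercepts": [b.tolist() for b in denoiser.intercepts],
        "holdout_loss": denoiser.holdout_loss,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> ToyDenoiser:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {payload.get('version')}")
    return ToyDenoiser(
        dim=int(payload["dim"]),
        sigma_data=float(payload["sigma_data"]),
        coefs=[np.asarray(W, dtype=float) for W in payload["coefs"]],
        intercepts=[np.asarray(b, dtype=float) for b in payload["intercepts"]],
        holdout_loss=payload.get("holdout_loss"),
    )
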