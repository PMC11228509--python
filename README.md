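# atomflow

All-atom protein generative sampling with a sidechain **superposition**:
a variance-exploding, score-based framework in which structure and
sequence are designed together, plus the guidance, likelihood and
structure-quality machinery around it.

## The problem

Most protein structure generative models design a backbone first and add
sidechains afterwards, even though sidechains carry most of a protein's
function. Designing all atoms at once runs into a chicken-and-egg
problem: the amino-acid identity of each residue determines *which*
sidechain atoms exist, but the identity is itself being designed. This
package implements a sampling scheme that resolves the circularity by
denoising a **superposition** of all 20 candidate sidechains per residue
("atom73": 5 shared slots N, CA, C, CB, O plus 68 amino-acid-specific
sidechain slots). At every denoising step an evolving sequence estimate
**collapses** the superposition to a concrete all-atom structure
(atom37 layout), the denoiser refines it, and the refined estimate is
scattered back. Each candidate sidechain is denoised only when its amino
acid is selected, so different atoms take different integration step
sizes; the shared backbone is denoised at every step.

The package is aimed at methods developers: every stage — forward
noising, denoising score matching with preconditioning, the stochastic
ODE sampler, sequence codesign, conditional guidance, change-of-variables
likelihoods, and the evaluation metrics — is exercised end to end at desk
scale using closed-form *oracle* denoisers (exact posterior means for
Gaussian and Gaussian-mixture data) and ideal-geometry synthetic
structures, so correctness is testable against analytic results without
any trained network or external data.

## The model

Noise level and time are identified, sigma(t) = t. The forward process
adds isotropic Gaussian noise to centered atom coordinates,
p_sigma = p_0 * N(0, sigma^2 I); sampling integrates the probability-flow
ODE

    dx = -sigma * grad_x log p_sigma(x) dsigma,
    grad_x log p_sigma(x) = (D(x, sigma) - x) / sigma^2,

where D is any denoiser (the optimal one is the posterior mean
E[x0 | x]). The sampler is a stochastic Euler scheme on a rho-warped
noise ladder with per-step noise injection (*s_churn*) and a score
multiplier (*step_scale*, an inverse temperature: scaling the score by
beta samples the beta-tempered density). Training uses a single weighted
denoising score-matching loss, EDM-style preconditioning
(c_skip, c_out, c_in, c_noise, lambda = 1/c_out^2), log-normal training
noise levels, and random-rotation augmentation. Because the ODE is a
continuous normalizing flow, exact log-likelihoods follow by integrating
the velocity divergence; per-atom likelihoods (nats/atom) filter
low-quality samples (default threshold 5 nats/atom).

Conditional generation supports three modes on arbitrary atom subsets
(all-atom, backbone-only, or sidechain *tip atoms* — the functional
groups after the last rotatable bond): replacement guidance,
reconstruction guidance through the denoiser Jacobian, and annealed
Metropolis-adjusted Langevin sampling.

## Worked example

```python
import numpy as np
from atomflow import (GaussianOracle, NoiseSchedule, SamplerConfig,
                      sample_allatom)
from atomflow.seqdesign import ToySequencePredictor
from atomflow.synthetic import make_ideal_helix
from atomflow.metrics import bond_geometry_stats, clash_fraction
from atomflow.likelihood import log_likelihood

# all-atom structure/sequence codesign on a Gaussian toy with the exact
# posterior-mean denoiser standing in for a trained network
schedule = NoiseSchedule(sigma_max=20.0, n_steps=100, sigma_data=1.0)
config = SamplerConfig(schedule=schedule, s_churn=10.0, seed=1)
denoiser = GaussianOracle(mean=0.0, var=1.0)
structure, sequence, log = sample_allatom(
    denoiser, ToySequencePredictor(), length=8, config=config)
print("designed sequence:", sequence)          # designed sequence: WGWWGWWW
print("atoms in structure:", structure.n_atoms)  # atoms in structure: 92

# geometry of an ideal helix fixture: every bond at its reference value
helix = make_ideal_helix(12, sequence="ASGVTLASGVTL")
stats = bond_geometry_stats(helix)
print(f"bond-length RMSE: {stats.bond_length_rmse:.2e} A")   # 6.35e-16 A
print(f"clash percentage: {clash_fraction(helix):.1f}%")     # 0.0%

# exact CNF likelihood of a 1-D standard-normal "atom"
res = log_likelihood(denoiser, np.zeros(1),
                     NoiseSchedule(sigma_max=200.0), n_ode_steps=400)
print(f"{res['total_nats']:.4f} nats")  # -0.9190 (analytic -0.9190)
```

The designed sequence is whatever the toy template-fit predictor commits
to on Gaussian noise (here tryptophan/glycine rich — the toy data carry
no real sequence signal); the atom count is exactly the heavy-atom count
of that sequence, demonstrating the collapse contract. The helix numbers
show the geometry metrics agree exactly with the fixture generator's
ideal-value table, and the likelihood matches the closed-form Gaussian
density to 4 decimals.

A command-line interface mirrors the library:
`atomflow sample|repack|scaffold|likelihood|eval-geometry|self-consistency|train-toy|make-fixtures`
(each writes a manifest with the config hash and seed for
reproducibility).

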