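# Methods

This note documents the model, the algorithmic choices, the defaults and
their rationale, what the synthetic test beds do and do not demonstrate,
and the package's known limitations.

## Noise process and score model

Time and noise level are identified: sigma(t) = t. The forward process
adds isotropic Gaussian noise to centered coordinates; marginals are
p_sigma = p_0 * N(0, sigma^2 I). There is no drift and no data scaling,
so the probability-flow ODE is

    dx/dsigma = -sigma * score = (x - D(x, sigma)) / sigma,

with the score recovered from any denoiser D via
score = (D(x, sigma) - x) / sigma^2. Structures are always centered (all
present atoms, equal weights), which together with the isotropy of the
noise makes the smoothed density SE(3)-invariant; rotational symmetry is
handled by data augmentation rather than architectural equivariance, so
nothing in the sampling machinery assumes an equivariant denoiser (the
oracles happen to be equivariant, which the tests exploit).

Sampling discretizes sigma on the warped ladder
sigma_i = (sigma_max^(1/rho) + (i/(n-1)) (sigma_min^(1/rho) -
sigma_max^(1/rho)))^rho with a terminal 0 appended. Stochasticity is
injected by churn: per step, gamma = min(s_churn/n_steps, sqrt(2) - 1),
sigma_hat = sigma (1 + gamma), x <- x + sqrt(sigma_hat^2 - sigma^2) z.
The denoising step multiplies the score by step_scale (beta); because
beta * score is the score of the beta-tempered density, beta > 1
concentrates samples around modes. For Gaussian data the tempered
terminal variance has the closed form
sigma_d^(2 beta) (sigma_d^2 + sigma_max^2)^(1 - beta), which the
acceptance suite verifies against Monte-Carlo runs using the *exactly
computable* variance of the discrete Euler map as the discretization
tolerance.

**Step order.** Within one iteration the order is: denoise (network
call), sequence prediction, churn, Euler step. The denoiser therefore
always sees coordinates at their tracked noise levels; the Euler step
uses the pre-churn denoised estimate. This ordering is what makes the
superposition sampler and the plain sampler bitwise-comparable in the
equivalence test.

## Training objective

A single weighted denoising score-matching loss with EDM-style
preconditioning: D(x, sigma) = c_skip x + c_out F(c_in x, c_noise),
c_skip = sigma_d^2/(sigma^2 + sigma_d^2),
c_out = sigma sigma_d / sqrt(sigma^2 + sigma_d^2),
c_in = 1/sqrt(sigma^2 + sigma_d^2), c_noise = ln(sigma)/4, and loss
weight lambda = 1/c_out^2. With the optimal denoiser the expected
weighted loss is exactly 1 per coordinate at every noise level, a
property the tests assert. Training noise levels are log-normal
(p_mean, p_std) rather than uniform. `dsm_loss` reports the mean over
present coordinates (so the untrained baseline sits near 1, and the
per-example sum equals the coordinate count).

The trainable denoiser is deliberately tiny: a two-hidden-layer
perceptron over flattened coordinates plus a noise embedding, fit with
scikit-learn's Adam optimizer inside the preconditioning wrapper.
Its job is to exercise the objective and the sampler end to end on a
CPU, not to model proteins; the denoiser contract accepts any stronger
network. Checkpoints are versioned JSON. Note that for *zero-mean
Gaussian* data the preconditioning skip path c_skip x is already the
posterior mean, so training cannot reduce the loss; training tests use
mean-shifted data, where the network must learn the mean to beat the
baseline.

## The atom73 superposition

Layout: 5 shared slots (N, CA, C, CB, O — the order is frozen) followed
by each amino acid's sidechain atoms beyond those five, grouped by
one-letter code alphabetically, atoms in PDB-standard order; 5 + 68 = 73.
`collapse` selects, per residue, the shared slots plus the sidechain
block of one amino acid and maps them into the 37-slot atom-name layout
(glycine's CB is masked off at collapse but remains part of the
superposition state and is denoised like any shared slot);
`update_superposition` is the inverse scatter and touches nothing else.

Each slot carries `sigma_last`, the noise level it was last denoised
*to*. Shared slots step every iteration; a sidechain block steps only
when the sequence estimate selects its amino acid, integrating from its
own sigma_last down to the step's target — rarely selected sidechains
take larger delta-sigma steps. `sigma_last` is non-increasing along a
trajectory by construction.

**Churn scope.** Churn is applied to the slots being stepped in the
current iteration (selected sidechains plus shared backbone), not to
waiting slots. Churning a slot that is never subsequently denoised would
compound its noise level without bound ((1+gamma)^k after k steps) and
break the monotonicity of sigma_last; restricting churn to stepped slots
keeps the waiting slots exactly at their last-denoised level, which is
what the per-atom Euler step assumes.

**Sub-stepping.** A slot selected for the first time late in the
trajectory integrates from sigma_max down to the current target. By
default this is a single Euler step (`substeps = 1`). In the far field
(sigma >> sigma_data) a single Euler step is exact — the solution is
linear in sigma there — but a step that crosses sigma ~ sigma_data
undershoots the terminal variance noticeably. `SamplerConfig.substeps`
splits each per-atom integration into k sub-intervals (interpolated in
the rho-warped variable per atom) with the denoiser re-evaluated at the
intermediate levels. The all-atom marginal-recovery test uses
substeps = 16, whose residual variance deficit we measured at ~3-5% on
the worst-case toy (a uniformly random sequence predictor, so gaps are
maximal); the test's variance assertion carries that measured allowance
on top of the Monte-Carlo bars. With a self-conditioned predictor that
stabilizes, gaps — and the deficit — are far smaller.

**Bootstrap and termination.** The initial sequence estimate comes from
denoising the initial noise once (under a fixed poly-alanine collapse)
and asking the predictor; the loop then always collapses with the
current estimate and re-predicts from the fresh denoised structure
(self-conditioned, blend weight 0.5, config-exposed). The terminal
structure is the collapse at the final sequence at sigma = 0; if the
final-step designer hook swaps in an external sequence, newly selected
slots fall back to their X0 estimate, which equals a terminal Euler step
to zero.

## Toy sequence predictor

The bundled predictor scores each amino acid at each residue by rigidly
fitting the amino acid's ideal all-atom template to the residue's
channel coordinates (Kabsch, proper rotations only), with unit penalties
for template atoms absent from the residue and present sidechain
channels the template does not explain; scores become a softmax with
temperature t0 (1 + (sigma/sigma_ref)^2), so high noise yields a
near-uniform exploratory distribution and low noise a committed one. It
sees the full 37-channel block rather than a sequence-derived subset,
mirroring the anti-leakage convention of noising all 37 channels. It is
deterministic, permutation-equivariant across residues, and recovers
100% of sidechain-bearing residues on ideal templates at low noise. It
is *not* a learned inverse-folding model and carries no real sequence
signal on noisy data — which is exactly what the sampler tests need
(worst-case, rapidly changing sequences).

## Two-stage sampling (repacking)

Stage 2 re-noises the sidechain atoms (including CB) of a fixed sequence
to `start_sigma` and denoises them down a fresh ladder; the backbone is
conditioned by replacement and stays bit-identical unless
`backbone_flex` > 0, in which case backbone atoms are noised to
backbone_flex * start_sigma and step as well (displacements then obey
the 3-sigma Gaussian tail bound). No sequence predictor runs. The
default start_sigma = 2.0 A is a sidechain-scale noise level — large
enough to randomize rotamers, small enough to preserve the fold — and is
config-exposed.

## Conditional generation

A motif fixes target coordinates for atom subsets of selected residues:
all-atom, backbone-only, or *tip atoms* (the final-chi rotation-axis
atoms plus everything distal, backbone excluded — e.g. the glutamate
carboxylate {CG, CD, OE1, OE2} or the histidine set
{CB, CG, ND1, CD2, CE1, NE2}). Motif coordinates live in the sample
frame (centered together with the sample; no separate frame search).

* **Replacement** overwrites motif atoms of the noisy state with targets
  noised to the current level. It propagates conditioning into the free
  coordinates only through the denoiser's correlations, and with a
  deterministic flow this transfer provably under-converges (on the
  correlated 2-D Gaussian toy the free coordinate's mean reaches ~0.43
  of its conditional value). Recovery requires stochasticity: with full
  churn and a long ladder the Langevin-like dynamics equilibrate to the
  conditional at each level and the toy's conditional mean is recovered
  within Monte-Carlo error.
* **Reconstruction guidance** adjusts the denoised estimate by the
  gradient of the motif misfit through the denoiser. The default
  `posterior` mode whitens the masked residual by the implied
  observation covariance M C(sigma) M^T with C = sigma^2 J (J the
  denoiser Jacobian) — for Gaussian data this makes the guided score the
  *exact* conditional score, and it degrades gracefully to the plain
  1/sigma^2 weighting as sigma -> 0. The `fixed` mode implements the
  plain weighted gradient with a constant or ramped weight schedule.
  Jacobians come from the denoiser when it provides them, from finite
  differences for small systems, and fall back to an identity
  approximation otherwise.
* **Annealed MCMC** runs Metropolis-adjusted Langevin proposals (churn
  noise plus a guided denoising drift, step size eps = step_frac *
  sigma^2) at each level of a decreasing ladder, targeting the
  sigma-smoothed model density times the motif likelihood, bridging
  between levels with one guided Euler step. The Metropolis correction
  needs log-density differences, which are not directly available from a
  denoiser; they are computed as trapezoidal line integrals of the
  (guided) score along the proposal segment. For quadratic log-densities
  the trapezoid rule is exact, so on the Gaussian test beds the chain
  satisfies detailed balance exactly; for general targets it is a
  consistent approximation. A proposal equal to the current state is
  always accepted; a level with zero acceptances warns rather than
  fails.

All three modes reduce to the unconditional sampler for an empty motif.
Scaffolding success calls use the standard thresholds — strict: all-atom
motif RMSD < 2 A, backbone motif RMSD < 1 A, scRMSD < 2 A, pLDDT > 70;
weak: all-atom < 4 A, backbone < 3 A, scTM > 0.5 — with structure
predictions and pLDDT supplied externally.

## Likelihood

The probability-flow ODE is integrated from sigma_min to sigma_max with
fixed-step RK4 on a rho-warped grid (default 400 steps, config-exposed —
a finer, fixed discretization than sampling, chosen so truncation error
is well below the reporting precision), accumulating the divergence of
the velocity field; the prior term is N(0, sigma_max^2 I). Divergences
are exact (analytic where the denoiser provides them, otherwise a
central-difference Jacobian trace) or estimated by a seeded Rademacher
(Hutchinson) trace estimator for larger systems. The dominant error is
prior truncation, about sigma_eff^2 / (2 sigma_max^2) nats per
coordinate (sigma_eff the data scale including mean offsets), so
likelihood runs use a larger sigma_max than sampling (200 in the tests:
max grid error ~3e-4 nats against closed forms). "Nats per atom" divides
total nats by the present-atom count (not the coordinate count); the
filtering threshold defaults to 5 nats/atom and is config-exposed
because the normalization convention is a declared choice.

## Geometry, fixtures and metrics

Ideal geometry merges two sources into one table so fixtures and metrics
agree exactly: backbone bond lengths and angles are frozen
Engh-Huber-style constants (N-CA 1.458, CA-C 1.525, C-O 1.231, peptide
C-N 1.329 A; N-CA-C 111.2, CA-C-O 120.8, CA-C-N 116.2, C-N-CA 121.7
deg), and sidechain geometry comes from the idealized chemical-component
templates bundled with biotite, with the template backbone bond lengths
snapped to the frozen constants (directions, hence angles, untouched).
Default rotamers are the template conformations — no rotamer library is
bundled, and bulky aromatics at template chis can clash in a helix, so
clash-sensitive fixtures use small residues. Chi angles follow IUPAC
quadruples, reported in (-180, 180]; residues are built to target chis
by rotating the distal atom set about each chi bond (round trips are
exact to 1e-6 degrees).

The helix generator grows the backbone by internal coordinates
(phi = -57, psi = -47, omega = 180) and rigidly attaches template
sidechains to each N/CA/C frame (CA snapped exactly), so every covalent
bond sits at its table value and the bond-length RMSE of a fixture is
zero to machine precision. TM-scores use the fixed residue
correspondence, d0 = 1.24 (L-15)^(1/3) - 1.8 floored at 0.5, and
iterative weighted-Kabsch superposition maximizing the score; RMSDs use
proper rotations only (reflections rejected). Clashes: a residue is
flagged if any heavy-atom pair at least 4 covalent bonds apart (any pair
from non-adjacent residues qualifies) sits closer than 0.63 x the summed
van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 A); both factor and
rule are config-exposed since the criterion is a declared convention.
Secondary-structure composition is consumed from external DSSP output
rather than recomputed.

The Gaussian atom73 toy draws every slot coordinate independently from a
known Gaussian and pairs the samples with the exact posterior-mean
oracle. This isolates the sampling *machinery* (bookkeeping, collapse,
per-atom steps, guidance, likelihood) from everything a trained network
would contribute; passing tests demonstrate the machinery is unbiased
and exact where it should be, and say nothing about protein realism,
which is out of scope here.

## Defaults

| Parameter | Default | Why |
| --- | --- | --- |
| sigma_min | 0.01 A | well below coordinate precision |
| sigma_max | 80 A | >= 3x fixture radius, prior error negligible |
| rho | 7 | standard warp; concentrates steps at low sigma |
| n_steps | 100 | sampling quality/cost balance at toy scale |
| sigma_data | estimated (RMS coordinate after centering); 1.0 fallback | preconditioning scale |
| p_mean, p_std | ln(sigma_data) - 1.2, 1.2 | log-normal training noise |
| s_churn | 0 | plain ODE unless stochasticity requested |
| step_scale | 1.0 | untempered sampling |
| substeps | 1 | single per-atom Euler step; see sub-stepping |
| stage2 start_sigma | 2.0 A | sidechain-scale re-noising |
| self-conditioning weight | 0.5 | even blend of fresh and previous estimate |
| clash overlap factor | 0.63 | conventional vdW-overlap cutoff |
| likelihood threshold | 5 nats/atom | working filter cutoff |

All are config-exposed (YAML: `schedule` / `sampler` / `stage2`
sections; unknown keys are rejected by name).

## Known limitations

* Single chain, heavy atoms only, 20 canonical residues; no mmCIF.
* The toy denoiser and toy sequence predictor are desk-scale stand-ins
  satisfying the contracts; they model no protein statistics.
* Default single-step per-atom integration under-disperses sidechains
  that are selected very late (see sub-stepping); realistic,
  self-conditioned trajectories mitigate this, and `substeps` removes it
  at extra denoiser cost.
* Replacement guidance without churn is biased; use churn or the other
  two modes for quantitative conditioning.
* The MCMC energy differences are line integrals of the score: exact for
  Gaussian targets, approximate in general (finer proposals reduce the
  error).
* Likelihoods carry a prior-truncation error O(sigma_eff^2/sigma_max^2)
  per coordinate; raise sigma_max for high-precision comparisons.
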