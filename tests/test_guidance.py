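"""Motifs, the three conditioning modes, and scaffolding success calls."""

import numpy as np
import pytest

from atomflow import (
    GaussianOracle,
    MultivariateGaussianOracle,
    NoiseSchedule,
    SamplerConfig,
    sample_ode,
)
from atomflow.guidance import (
    MCMCConfig,
    Motif,
    annealed_mcmc,
    mala_log_alpha,
    read_motif,
    replacement_guidance,
    reconstruction_guidance,
    scaffold_success,
    success_flags,
    write_motif,
)
from atomflow.sampling import SeededNoise
from atomflow.synthetic import make_ideal_helix

RHO = 0.8
MVG = MultivariateGaussianOracle(np.zeros(2), np.array([[1.0, RHO], [RHO, 1.0]]))
MASK = np.array([True, False])
TGT = np.array([1.0, 0.0])


# --------------------------------------------------------------- motifs

def test_motif_from_structure_modes(mixed_helix):
    m_all = Motif.from_structure(mixed_helix, [3, 4], mode="all-atom")
    m_bb = Motif.from_structure(mixed_helix, [3, 4], mode="backbone")
    m_tip = Motif.from_structure(mixed_helix, [3], mode="tip")  # V -> CB,CG1,CG2
    assert m_bb.n_atoms == 8
    assert {n for _, n in m_tip.atoms} == {"CB", "CG1", "CG2"}
    assert m_all.n_atoms > m_bb.n_atoms
    with pytest.raises(IndexError):
        m_all.mask_and_targets(2)


def test_motif_file_roundtrip(tmp_path, mixed_helix):
    m = Motif.from_structure(mixed_helix, [2, 5], mode="backbone")
    p = tmp_path / "motif.txt"
    write_motif(m, p)
    back = read_motif(p)
    assert back.atoms == m.atoms
    np.testing.assert_allclose(back.targets, m.targets, atol=1e-3)
    p.write_text("0 CA 1.0 2.0\n")
    with pytest.raises(ValueError, match="expected"):
        read_motif(p)


# ------------------------------------------------------------ guidance

def test_replacement_guidance_basics(rng):
    x = rng.standard_normal((4, 2))
    out = replacement_guidance(x, (MASK, TGT), 0.0, seed=0)
    np.testing.assert_array_equal(out[:, 0], 1.0)  # sigma 0 -> exact targets
    np.testing.assert_array_equal(out[:, 1], x[:, 1])  # others untouched
    empty = (np.zeros(2, bool), TGT)
    np.testing.assert_array_equal(replacement_guidance(x, empty, 1.0, seed=0), x)


def test_reconstruction_guidance_basics(rng):
    x = rng.standard_normal(2)
    x0 = MVG(x, 1.0)
    out = reconstruction_guidance(x, x0, (MASK, TGT), 1.0, weight=0.0, denoiser=MVG)
    np.testing.assert_array_equal(out, x0)
    # zero gradient when the motif is already satisfied
    x0_sat = np.array([1.0, 0.3])
    out = reconstruction_guidance(x, x0_sat, (MASK, TGT), 1.0, denoiser=MVG)
    np.testing.assert_allclose(out, x0_sat, atol=1e-12)
    empty = (np.zeros(2, bool), TGT)
    np.testing.assert_array_equal(
        reconstruction_guidance(x, x0, empty, 1.0, denoiser=MVG), x0
    )
    with pytest.raises(ValueError):
        reconstruction_guidance(x, x0, (MASK, TGT), 1.0, weight=-1.0)


def conditional_check(x2, n, label, tol_bias=0.0):
    se3 = 3 * np.sqrt((1 - RHO**2) / n)
    assert abs(x2.mean() - RHO * 1.0) < se3 + tol_bias, label


def test_replacement_recovers_conditional_gaussian():
    """Pinning x1 = y during stochastic sampling leaves x2 ~ N(rho y, .)."""
    B = 4000
    sched = NoiseSchedule(sigma_min=0.01, sigma_max=5.0, n_steps=600, sigma_data=1.0)
    cfg = SamplerConfig(schedule=sched, seed=2, s_churn=1e9)
    noise = SeededNoise(21)
    pre = lambda x, s, i: replacement_guidance(  # noqa: E731
        x, (MASK, TGT), s, z=noise.draw(i, "guidance", x.shape)
    )
    x = sample_ode(MVG, (B, 2), cfg, pre_fn=pre)
    conditional_check(x[:, 1], B, "replacement")
    np.testing.assert_allclose(x[:, 0], 1.0, atol=0.05)


def test_reconstruction_recovers_conditional_gaussian():
    B = 4000
    sched = NoiseSchedule(sigma_min=0.01, sigma_max=80.0, n_steps=150, sigma_data=1.0)
    cfg = SamplerConfig(schedule=sched, seed=3)
    gfn = lambda x, x0, s, i: reconstruction_guidance(  # noqa: E731
        x, x0, (MASK, TGT), s, denoiser=MVG, mode="posterior"
    )
    x = sample_ode(MVG, (B, 2), cfg, guidance_fn=gfn)
    conditional_check(x[:, 1], B, "reconstruction")


def test_mcmc_recovers_conditional_gaussian():
    sched = NoiseSchedule(sigma_min=0.01, sigma_max=20.0, n_steps=40, sigma_data=1.0)
    s, info = annealed_mcmc(
        MVG, (MASK, TGT), sched, MCMCConfig(seed=4), n_chains=4000, dim=2
    )
    conditional_check(s[:, 1], 4000, "mcmc")
    assert len(info["acceptance_rates"]) == 40


def test_mcmc_motif_free_matches_data_moments():
    """Detailed-balance sanity: without a motif the chain equilibrates to the
    data Gaussian."""
    sched = NoiseSchedule(sigma_min=0.01, sigma_max=20.0, n_steps=40, sigma_data=1.0)
    empty = (np.zeros(2, bool), np.zeros(2))
    s, _ = annealed_mcmc(
        GaussianOracle(0.0, 1.0), empty, sched, MCMCConfig(seed=5),
        n_chains=4000, dim=2,
    )
    v = s.ravel()
    assert abs(v.mean()) < 3 / np.sqrt(v.size)
    assert abs(v.var() - 1.0) < 3 * np.sqrt(2 / v.size)


def test_mcmc_accepts_identity_proposal(rng):
    x = rng.standard_normal((5, 2))
    g = rng.standard_normal((5, 2))
    la = mala_log_alpha(x, x.copy(), g, g.copy(), eps=0.3)
    np.testing.assert_allclose(la, 0.0, atol=1e-12)


def test_mcmc_zero_acceptance_warns():
    class RejectingOracle(GaussianOracle):
        pass

    sched = NoiseSchedule(sigma_min=0.5, sigma_max=1.0, n_steps=2, sigma_data=1.0)
    # absurd step size forces rejections but must only warn
    cfg = MCMCConfig(n_levels=2, proposals_per_level=2, step_frac=2e4, seed=6)
    empty = (np.zeros(1, bool), np.zeros(1))
    with pytest.warns(UserWarning, match="no acceptances"):
        annealed_mcmc(GaussianOracle(0.0, 1.0), empty, sched, cfg, n_chains=2, dim=1)


# ----------------------------------------------------- scaffold success

def test_success_flags_thresholds():
    # all-atom 3.0, backbone 2.0, scTM 0.6: weak success only
    strict, weak = success_flags(3.0, 2.0, 1.0, 0.6, 90.0)
    assert (strict, weak) == (False, True)
    # scRMSD 2.5 with everything else passing: strict fails, weak on its own
    strict, weak = success_flags(1.0, 0.5, 2.5, 0.8, 90.0)
    assert (strict, weak) == (False, True)
    strict, weak = success_flags(1.0, 0.5, 1.0, 0.8, 90.0)
    assert (strict, weak) == (True, True)
    strict, weak = success_flags(1.0, 0.5, 1.0, 0.8, 60.0)  # pLDDT gate
    assert (strict, weak) == (False, True)


def test_scaffold_success_self_prediction(mixed_helix):
    motif = Motif.from_structure(mixed_helix, [4, 5, 6], mode="all-atom")
    res = scaffold_success(mixed_helix, motif, mixed_helix, plddt=100.0)
    assert res["strict_success"] and res["weak_success"]
    assert res["motif_rmsd_allatom"] < 1e-6
    assert res["scRMSD"] < 1e-6 and res["scTM"] > 0.999


def test_scaffold_success_missing_atoms_errors(mixed_helix):
    motif = Motif.from_structure(mixed_helix, [4], mode="all-atom")
    broken = mixed_helix.copy()
    broken.mask37[4, :] = False
    broken.mask37[4, [0, 1, 2, 4]] = True
    with pytest.raises(ValueError, match="motif"):
        scaffold_success(broken, motif, mixed_helix, plddt=100.0)
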