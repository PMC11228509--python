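"""Euler/churn step primitives, the superposition sampling loop, the
constant-sequence equivalence oracle, and stage-2 repacking."""

import numpy as np
import pytest
from scipy import stats

from atomflow import (
    GaussianOracle,
    GMMOracle,
    NoiseSchedule,
    SamplerConfig,
    SeededNoise,
    Stage2Config,
    churn,
    euler_denoise_step,
    sample_allatom,
    sample_backbone,
    sample_ode,
    sample_stage2_repack,
)
from atomflow.residues import AA1, AA_SLOT_MAPS
from atomflow.sampling import BACKBONE_SLOTS37, sample_backbone_ensemble
from atomflow.structure import selected_slot_mask, sequence_mask37
from atomflow.synthetic import make_ideal_helix


class ConstantPredictor:
    def __init__(self, seq):
        self.seq = seq

    def __call__(self, structure, sigma, prev=None, rng=None):
        return None, self.seq


class RandomPredictor:
    def __call__(self, structure, sigma, prev=None, rng=None):
        L = len(structure.sequence)
        return None, "".join(AA1[i] for i in rng.integers(0, 20, L))


# --------------------------------------------------------- primitives

def test_euler_step_examples(rng):
    x = rng.standard_normal(5)
    x0 = rng.standard_normal(5)
    np.testing.assert_allclose(euler_denoise_step(x, x0, 1.0, 0.0), x0, atol=1e-14)
    np.testing.assert_array_equal(euler_denoise_step(x, x, 1.0, 0.5), x)
    with pytest.raises(ValueError):
        euler_denoise_step(x, x0, 0.5, 0.5)


def test_churn_examples(rng):
    x = rng.standard_normal(4)
    out, s_hat = churn(x, 1.0, 0.0, seed=0)
    np.testing.assert_array_equal(out, x)
    assert s_hat == 1.0
    z = np.ones(4)
    out, s_hat = churn(x, 1.0, 0.1, z=z)
    assert s_hat == pytest.approx(1.1)
    np.testing.assert_allclose(out - x, np.sqrt(0.21), atol=1e-12)
    with pytest.raises(ValueError):
        churn(x, 1.0, -0.1, seed=0)


def test_churn_preserves_marginal():
    """Churning N(x0, sigma^2) samples yields N(x0, sigma_hat^2)."""
    rng = np.random.default_rng(0)
    sigma, gamma = 1.0, 0.3
    x = 2.0 + sigma * rng.standard_normal(100_000)
    out, s_hat = churn(x, sigma, gamma, rng=rng)
    ref = 2.0 + s_hat * rng.standard_normal(100_000)
    assert stats.ks_2samp(out, ref).pvalue > 1e-4


# ------------------------------------------------ equivalence oracle

def test_constant_sequence_matches_plain_sampler():
    """With a frozen sequence the superposition machinery is a no-op: the
    trajectory equals the plain sampler run on the collapsed atom set."""
    L, seq = 10, "LKEAVQHFST"
    sched = NoiseSchedule(sigma_max=80.0, n_steps=50, sigma_data=1.0)
    cfg = SamplerConfig(schedule=sched, s_churn=10.0, seed=3)
    den = GaussianOracle(0.0, 1.0)
    out, final_seq, log = sample_allatom(
        den, ConstantPredictor(seq), L, cfg, init_sequence=seq
    )
    assert final_seq == seq

    sel = selected_slot_mask(seq)

    class SlicedNoise(SeededNoise):
        # same stream, restricted to the collapsed slots
        def draw(self, step, tag, shape):
            full = SeededNoise.draw(self, step, tag, (L, 73, 3))
            return full[sel].reshape(shape)

    n_sel = int(sel.sum())
    x = sample_ode(den, (n_sel, 3), cfg, noise=SlicedNoise(cfg.seed))
    x73 = np.zeros((L, 73, 3))
    x73[sel] = x.reshape(-1, 3)
    expected = np.zeros_like(out.coords37)
    for i, aa in enumerate(seq):
        s73, s37 = AA_SLOT_MAPS[aa]
        expected[i, s37] = x73[i, s73]
    dev = np.abs(expected[out.mask37] - out.coords37[out.mask37]).max()
    assert dev < 1e-10


def test_output_atom_set_matches_final_sequence():
    sched = NoiseSchedule(sigma_max=20.0, n_steps=20, sigma_data=1.0)
    cfg = SamplerConfig(schedule=sched, seed=5)
    out, seq, _ = sample_allatom(
        GaussianOracle(0.0, 1.0), RandomPredictor(), 4, cfg
    )
    np.testing.assert_array_equal(out.mask37, sequence_mask37(seq))


def test_external_sequence_swap_and_length_check():
    sched = NoiseSchedule(sigma_max=20.0, n_steps=15, sigma_data=1.0)
    cfg = SamplerConfig(schedule=sched, seed=6)
    den = GaussianOracle(0.0, 1.0)
    out, seq, _ = sample_allatom(
        den, RandomPredictor(), 4, cfg, external_sequence="WYVK"
    )
    assert seq == "WYVK"
    np.testing.assert_array_equal(out.mask37, sequence_mask37("WYVK"))
    with pytest.raises(ValueError, match="length"):
        sample_allatom(den, RandomPredictor(), 4, cfg, external_sequence="WYV")


def test_sigma_last_bookkeeping():
    """Selected slots land on the step's target sigma; unselected sidechain
    slots keep their previous level; levels never increase."""
    sched = NoiseSchedule(sigma_max=20.0, n_steps=25, sigma_data=1.0)
    cfg = SamplerConfig(schedule=sched, seed=7)
    from atomflow.diffusion import discretize_sigmas

    sigmas = discretize_sigmas(sched)
    seen = {"prev": None, "ok_target": True, "ok_monotone": True, "ok_frozen": True}

    def cb(state):
        sel = selected_slot_mask(state.seq_hat)
        tgt = sigmas[state.step + 1]
        if not np.allclose(state.sp_t.sigma_last[sel], tgt):
            seen["ok_target"] = False
        if seen["prev"] is not None:
            prev = seen["prev"]
            if np.any(state.sp_t.sigma_last > prev + 1e-12):
                seen["ok_monotone"] = False
            if not np.array_equal(state.sp_t.sigma_last[~sel], prev[~sel]):
                seen["ok_frozen"] = False
        seen["prev"] = state.sp_t.sigma_last.copy()

    sample_allatom(
        GaussianOracle(0.0, 1.0), RandomPredictor(), 3, cfg, state_callback=cb
    )
    assert seen["ok_target"] and seen["ok_monotone"] and seen["ok_frozen"]


def test_allatom_marginal_recovery_gaussian_toy():
    """Terminal all-atom marginals track the per-slot data Gaussian despite
    intermittent sidechain updates (random-sequence predictor).

    Mean is checked at 3 Monte-Carlo SE; the pooled variance additionally
    carries a 5% allowance for the sub-stepped per-atom integrator's
    measured discretization error.
    """
    L, runs = 2, 300
    sched = NoiseSchedule(sigma_max=20.0, n_steps=100, sigma_data=1.0)
    den = GaussianOracle(0.0, 1.0)
    vals = []
    for r in range(runs):
        cfg = SamplerConfig(schedule=sched, seed=4000 + r, substeps=16)
        out, _, _ = sample_allatom(den, RandomPredictor(), L, cfg)
        vals.append(out.present_coords())
    v = np.concatenate(vals).ravel()
    assert abs(v.mean()) < 3 / np.sqrt(v.size)
    assert abs(v.var() - 1.0) < 3 * np.sqrt(2 / v.size) + 0.05


# ----------------------------------------------------- backbone model

def test_backbone_deterministic_under_seed(unit_schedule):
    cfg = SamplerConfig(schedule=unit_schedule, s_churn=5.0, seed=9)
    den = GaussianOracle(0.0, 1.0)
    a = sample_backbone(den, 6, cfg)
    b = sample_backbone(den, 6, cfg)
    np.testing.assert_array_equal(a.coords37, b.coords37)
    assert a.mask37[:, BACKBONE_SLOTS37].all() and a.mask37.sum() == 6 * 4


def test_backbone_matches_ensemble_engine(unit_schedule):
    cfg = SamplerConfig(schedule=unit_schedule, seed=10)
    den = GaussianOracle(0.0, 1.0)
    s = sample_backbone(den, 3, cfg)
    x = sample_ode(den, (3, 4, 3), cfg)
    np.testing.assert_array_equal(s.coords37[:, BACKBONE_SLOTS37], x)


def test_backbone_moment_recovery():
    sched = NoiseSchedule(sigma_max=20.0, n_steps=400, sigma_data=1.0)
    cfg = SamplerConfig(schedule=sched, seed=11)
    x = sample_backbone_ensemble(GaussianOracle(0.0, 1.0), 2, cfg, 400)
    v = x.ravel()
    assert abs(v.mean()) < 3 / np.sqrt(v.size)
    assert abs(v.var() - 1.0) < 3 * np.sqrt(2 / v.size)


def test_step_scale_shrinks_mode_spread_for_gmm():
    """Raising the inverse temperature concentrates samples around modes."""
    D = 6
    gmm = GMMOracle([0.5, 0.5], np.stack([3 * np.ones(D), -3 * np.ones(D)]), [1.0, 1.0])
    sched = NoiseSchedule(sigma_max=40.0, n_steps=300, sigma_data=1.0)
    spreads = []
    for beta in (1.0, 1.5, 2.0):
        cfg = SamplerConfig(schedule=sched, step_scale=beta, seed=12)
        x = sample_ode(gmm, (400, D), cfg)
        mode = np.where(x.mean(axis=1, keepdims=True) > 0, 3.0, -3.0)
        spreads.append(float(((x - mode) ** 2).mean()))
    assert spreads[0] > spreads[1] > spreads[2]


# ----------------------------------------------------------- stage 2

@pytest.fixture(scope="module")
def repack_setup():
    fixed = make_ideal_helix(8, sequence="ASLVKEST")
    mean = np.zeros((8, 37, 3))
    mean[fixed.mask37] = fixed.coords37[fixed.mask37]
    den = GaussianOracle(mean=mean, var=1e-4)  # oracle centered on the input
    sched = NoiseSchedule(sigma_max=80.0, n_steps=100, sigma_data=5.0)
    return fixed, den, sched


def test_repack_fixed_point(repack_setup):
    fixed, den, sched = repack_setup
    cfg = SamplerConfig(
        schedule=sched, seed=7, stage2=Stage2Config(start_sigma=2.0, n_steps=40)
    )
    out = sample_stage2_repack(den, fixed, cfg)
    np.testing.assert_array_equal(out.mask37, fixed.mask37)
    np.testing.assert_array_equal(
        out.coords37[:, BACKBONE_SLOTS37], fixed.coords37[:, BACKBONE_SLOTS37]
    )
    side = fixed.mask37.copy()
    side[:, BACKBONE_SLOTS37] = False
    rms = np.sqrt(((out.coords37[side] - fixed.coords37[side]) ** 2).mean())
    assert rms < 0.05  # discretization tolerance of the 40-step ladder


def test_repack_flexible_backbone_bounded(repack_setup):
    fixed, den, sched = repack_setup
    cfg = SamplerConfig(
        schedule=sched,
        seed=8,
        stage2=Stage2Config(start_sigma=2.0, n_steps=40, backbone_flex=0.5),
    )
    out = sample_stage2_repack(den, fixed, cfg)
    disp = np.linalg.norm(
        out.coords37[:, BACKBONE_SLOTS37] - fixed.coords37[:, BACKBONE_SLOTS37],
        axis=-1,
    )
    assert disp.max() > 0  # backbone allowed to move
    assert disp.max() < 3 * 0.5 * 2.0  # Gaussian tail bound at start level


def test_repack_missing_backbone_errors(repack_setup):
    fixed, den, sched = repack_setup
    broken = fixed.copy()
    broken.mask37[0, 0] = False
    cfg = SamplerConfig(schedule=sched, seed=1)
    with pytest.raises(ValueError, match="backbone"):
        sample_stage2_repack(den, broken, cfg)


def test_sampler_config_validation(unit_schedule):
    with pytest.raises(ValueError):
        SamplerConfig(schedule=unit_schedule, s_churn=-1.0)
    with pytest.raises(ValueError):
        SamplerConfig(schedule=unit_schedule, step_scale=0.0)
    assert SamplerConfig(schedule=unit_schedule, s_churn=1e9).gamma() == pytest.approx(
        np.sqrt(2) - 1
    )
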