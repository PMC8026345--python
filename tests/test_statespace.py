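import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import log_ndtr

from navlearn.cohort import (
    DEFAULT_ARCHETYPES,
    build_schedule,
    simulate_subject,
)
from navlearn.io import SamplerConfig, TrialRecord, records_to_frame
from navlearn.statespace import (
    ModelBuildError,
    diagnose,
    fit_block_model,
    fit_trial_model,
    sample_prior_states,
)

from .conftest import TEST_CFG


def _constant_trials(good_subject, value=50.0):
    trials, _ = good_subject
    const = trials.copy()
    obs = ~const["missing"]
    const.loc[obs, "abs_error"] = value
    const.loc[obs, "signed_error"] = value
    return const


@pytest.mark.parametrize("fitter", [fit_block_model, fit_trial_model],
                         ids=["block", "trial"])
def test_draw_counts_match_sampler_config(good_subject, fitter):
    trials, _ = good_subject
    cfg = SamplerConfig(chains=2, iterations=300, warmup=150, seed=1)
    post = fitter(trials, cfg)
    assert post.n_chains == 2
    assert post.n_draws == 150
    assert post.total_draws == cfg.total_draws == 300


@pytest.mark.parametrize("fitter", [fit_block_model, fit_trial_model],
                         ids=["block", "trial"])
def test_constant_data_recovers_the_constant(good_subject, fitter):
    """Noise-free data at 50 deg: every state estimate within 5% of 50."""
    post = fitter(_constant_trials(good_subject), TEST_CFG)
    states = post.state_draws_deg().mean(axis=0)
    assert np.all(np.abs(states - 50.0) / 50.0 < 0.05)


def test_block_states_recover_planted_trajectory(good_subject, block_posterior):
    """Posterior mean of exp(mu_b) within 2 posterior SDs of the planted
    state in at least 7 of 8 blocks."""
    _, truth = good_subject
    states = block_posterior.state_draws_deg()
    mean, sd = states.mean(axis=0), states.std(axis=0)
    hits = np.abs(mean - truth) <= 2.0 * sd
    assert hits.sum() >= 7


def test_cross_model_consistency_on_low_noise_data(behavioral_spec):
    """On clean data the block state matches the block-average of the
    trial-wise states within posterior uncertainty."""
    arch = dataclasses.replace(DEFAULT_ARCHETYPES["good"], trial_noise_sd=0.15)
    plan = build_schedule(behavioral_spec, seed=21)
    trials, _ = simulate_subject(arch, plan, "young", seed=22,
                                 spec=behavioral_spec)
    pb = fit_block_model(trials, TEST_CFG)
    pt = fit_trial_model(trials, TEST_CFG)
    blocks = np.asarray(pt.meta["block_of_trial"])
    t_states = pt.state_draws_deg()
    t_block = np.column_stack(
        [t_states[:, blocks == b].mean(axis=1) for b in range(1, 9)])
    b_states = pb.state_draws_deg()
    gap = np.abs(b_states.mean(axis=0) - t_block.mean(axis=0))
    spread = np.sqrt(b_states.std(axis=0) ** 2 + t_block.std(axis=0) ** 2)
    assert np.all(gap <= 3.0 * spread)


def test_missing_trials_are_imputed_not_dropped(behavioral_spec):
    arch = dataclasses.replace(DEFAULT_ARCHETYPES["weak"], missing_prob=0.15)
    plan = build_schedule(behavioral_spec, seed=31)
    trials, _ = simulate_subject(arch, plan, "old", seed=32,
                                 spec=behavioral_spec)
    assert trials["missing"].any()
    post = fit_block_model(trials, SamplerConfig(2, 300, 150, 0))
    assert post.eta.shape[2] == 96  # every scheduled trial, observed or not
    miss_idx = np.flatnonzero(trials.sort_values(["block", "trial_in_block"])
                              ["missing"].to_numpy())
    # missing-trial eta follows its half-normal prior: located at or above
    # the log block mean
    blocks = trials.sort_values(["block", "trial_in_block"])["block"].to_numpy()
    for t in miss_idx[:3]:
        b = blocks[t]
        block_mean = trials.loc[(trials["block"] == b) & ~trials["missing"],
                                "abs_error"].mean()
        draws = post.eta[:, :, t].reshape(-1)
        assert (draws >= math.log(block_mean) - 1e-9).all()


def test_block_with_no_observations_requires_explicit_fallback():
    recs = []
    for b in range(1, 4):
        for t in range(1, 5):
            missing = b == 2
            recs.append(TrialRecord(
                "S1", "young", b, t, "I1", "D1", "T1", "retrieval",
                abs_error=None if missing else 40.0,
                signed_error=None if missing else 40.0,
                missing=missing))
    trials = records_to_frame(recs)
    with pytest.raises(ModelBuildError, match="fallback"):
        fit_block_model(trials, SamplerConfig(2, 200, 100, 0))
    post = fit_block_model(trials, SamplerConfig(2, 200, 100, 0),
                           missing_block_fallback=True)
    assert post.n_states == 3


def test_too_few_observed_blocks_rejected():
    recs = [TrialRecord("S1", "young", 1, t, "I1", "D1", "T1", "retrieval",
                        abs_error=30.0, signed_error=30.0)
            for t in range(1, 13)]
    with pytest.raises(ModelBuildError, match="2 blocks"):
        fit_block_model(records_to_frame(recs), SamplerConfig(2, 200, 100, 0))


def test_prior_state_centers_near_chance():
    draws = sample_prior_states(4000, n_blocks=8, chance_level=90.0, seed=0)
    assert 60.0 <= np.median(draws[:, 0]) <= 135.0


# ---------------------------------------------------------------------------
# sampler correctness against a brute-force oracle
# ---------------------------------------------------------------------------


def _rw_metropolis_oracle(log_y, blocks, n_blocks, seed, n_iter=250_000):
    """Independent random-walk Metropolis on the collapsed posterior
    (mu_1..mu_B, log s, log sigma_mu); deliberately naive."""
    u = math.log(180.0)
    m0 = math.log(90.0)
    rng = np.random.default_rng(seed)

    def logpost(th):
        mu, ls, lsmu = th[:n_blocks], th[n_blocks], th[n_blocks + 1]
        s, smu = math.exp(ls), math.exp(lsmu)
        lp = -0.5 * (mu[0] - m0) ** 2
        lp += -0.5 * np.sum(np.diff(mu) ** 2) / smu**2 - (n_blocks - 1) * lsmu
        lp += 2 * ls - 0.5 * s * s       # Rayleigh prior on s (polar radius)
        lp += -0.5 * smu * smu + lsmu    # half-normal prior on sigma_mu
        z = (log_y - mu[blocks]) / s
        lp += float(np.sum(-ls - 0.5 * z * z - log_ndtr((u - mu[blocks]) / s)))
        return lp

    th = np.concatenate([np.full(n_blocks, log_y.mean()),
                         [math.log(0.5)], [math.log(0.2)]])
    lp = logpost(th)
    step = np.concatenate([np.full(n_blocks, 0.12), [0.06], [0.3]])
    keep = []
    for i in range(n_iter):
        prop = th + step * rng.standard_normal(n_blocks + 2)
        lpp = logpost(prop)
        if math.log(rng.random() + 1e-300) < lpp - lp:
            th, lp = prop, lpp
        if i >= n_iter // 4 and i % 25 == 0:
            keep.append(th.copy())
    return np.array(keep)


def test_block_sampler_agrees_with_brute_force_oracle():
    """Posterior summaries from the structured sampler match a naive
    random-walk Metropolis run on the same (collapsed) posterior."""
    rng = np.random.default_rng(77)
    n_blocks, per_block = 4, 10
    states = np.array([85.0, 70.0, 55.0, 45.0])
    recs = []
    for b in range(n_blocks):
        for t in range(per_block):
            y = float(np.clip(rng.lognormal(math.log(states[b]), 0.45), 1, 179.9))
            recs.append(TrialRecord("S1", "young", b + 1, t + 1, "I1", "D1",
                                    "T1", "retrieval", abs_error=y,
                                    signed_error=y))
    trials = records_to_frame(recs)
    cfg = SamplerConfig(chains=4, iterations=3000, warmup=1000, seed=5)
    post = fit_block_model(trials, cfg)
    ours = post.state_draws_deg()

    obs = trials.sort_values(["block", "trial_in_block"])
    log_y = np.log(obs["abs_error"].to_numpy(float))
    blocks = obs["block"].to_numpy(int) - 1
    oracle = _rw_metropolis_oracle(log_y, blocks, n_blocks, seed=3)
    oracle_states = np.exp(oracle[:, :n_blocks])

    ours_mean, oracle_mean = ours.mean(axis=0), oracle_states.mean(axis=0)
    pooled_sd = ours.std(axis=0)
    # agreement well within posterior spread (both carry MC error)
    assert np.all(np.abs(ours_mean - oracle_mean) < 0.35 * pooled_sd)
    s_ours = float(np.hypot(post.sigma_eta, post.sigma_y).mean())
    s_oracle = float(np.exp(oracle[:, n_blocks]).mean())
    assert s_ours == pytest.approx(s_oracle, abs=0.05)


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------


def _fake_posterior(mu):
    from navlearn.statespace import StateSpacePosterior

    chains, draws, b = mu.shape
    ones = np.full((chains, draws), 0.5)
    return StateSpacePosterior(
        model="block", mu=mu, eta=None, sigma_mu=ones, sigma_eta=None,
        sigma_y=ones, meta={"n_blocks": b})


def test_identical_stationary_chains_have_rhat_one():
    rng = np.random.default_rng(0)
    chain = rng.normal(0, 1, (1, 2000, 3))
    post = _fake_posterior(np.repeat(chain, 4, axis=0))
    rep = diagnose(post, ess_threshold=0.0)
    assert rep.rhat.loc[["mu[1]", "mu[2]", "mu[3]"]].max() == pytest.approx(1.0, abs=0.01)


def test_offset_chains_fail_and_agree_with_independent_rhat():
    rng = np.random.default_rng(1)
    base = rng.normal(0, 1, (1, 1000, 1))
    shifted = np.concatenate([base, base + 10.0], axis=0)
    post = _fake_posterior(shifted)
    rep = diagnose(post)
    assert rep.rhat.filter(like="mu").max() > 1.1
    assert not rep.passed
    # independent classic (non-rank) split-Rhat computation
    x = shifted[:, :, 0]
    halves = np.concatenate([x[:, :500], x[:, 500:]], axis=0)
    m, n = halves.shape
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    classic = math.sqrt(((n - 1) / n * w + b / n) / w)
    assert classic > 1.1


def test_single_chain_rhat_undefined(block_posterior):
    single = dataclasses.replace(
        block_posterior,
        mu=block_posterior.mu[:1], eta=block_posterior.eta[:1],
        sigma_mu=block_posterior.sigma_mu[:1],
        sigma_eta=block_posterior.sigma_eta[:1],
        sigma_y=block_posterior.sigma_y[:1])
    with pytest.raises(ValueError, match="2 chains"):
        diagnose(single)


def test_ess_positive_and_of_draw_order(block_posterior):
    rep = diagnose(block_posterior)
    assert (rep.ess > 0).all()
    # bulk ESS can exceed the raw draw count when updates are antithetic
    # (negative lag-1 autocorrelation), but stays of the same order
    assert (rep.ess <= 2.0 * block_posterior.total_draws).all()


def test_fitted_chains_mix_well(block_posterior):
    rep = diagnose(block_posterior)
    assert rep.max_rhat <= 1.05
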