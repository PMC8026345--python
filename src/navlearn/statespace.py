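"""Hierarchical Bayesian state-space models of block-wise spatial learning.

Model (block-wise, the primary variant)
---------------------------------------
Absolute pointing errors y_t (degrees) from one subject are modeled on
the log scale.  A hidden learning state mu_b follows a random walk over
learning blocks b = 1..B; an intermediate trial-effect layer eta_t
shrinks individual trials toward their block's state:

    mu_1   ~ Normal(log(chance_level), 1)
    mu_b   ~ Normal(mu_{b-1}, sigma_mu)            b = 2..B
    eta_t  ~ Normal(mu_{b(t)}, sigma_eta)          observed trials
    y_t    ~ LogNormal(eta_t, sigma_y),  conditioned on y_t <= 180
    eta_t  ~ log(ybar_b) + |Normal(0, 1)|          missing trials (timeouts)
    sigma_mu, sigma_eta, sigma_y ~ HalfNormal(0, 1)

where ybar_b is the observed mean error of block b.  Missing trials
contribute no likelihood term (a timeout has no outcome); their eta is
pure prior imputation anchored at the log block mean.  exp(mu_b) is the
learning state in degrees; 90 deg is chance under uniform pointing.

An absolute pointing error cannot exceed 180 deg, and near chance level
a non-negligible part of an untruncated lognormal would lie beyond that
bound, biasing the state downward; the model therefore conditions each
trial's outcome on the physical bound (marginally log y_t follows a
Normal(mu_b, sigma_eta^2 + sigma_y^2) truncated at log 180).

The trial-wise alternative drops eta and lets the state walk from trial
to trial: mu_t ~ Normal(mu_{t-1}, sigma_mu), y_t ~ LogNormal(mu_t,
sigma_y) conditioned on y_t <= 180.

Inference
---------
Without the truncation bound the model is linear-Gaussian in (mu, eta)
given the scales; the bounded likelihood differs from the Gaussian one
only by normal-CDF normalizers that depend on the state and the total
scale.  The sampler exploits this throughout:

* eta is integrated out analytically wherever possible (marginally each
  observed log error is Normal(mu_b, s^2) truncated, with
  s^2 = sigma_eta^2 + sigma_y^2) and re-drawn from its exact Gaussian
  conditional only when a draw is recorded;
* the state chain is proposed jointly by forward-filtering
  backward-sampling (FFBS) under a first-order exponential tilt of the
  CDF normalizers and accepted with the second-order remainder
  (acceptance near 1);
* the split of s into (sigma_eta, sigma_y) is likelihood-unidentified,
  and under the half-normal priors its polar angle is exactly uniform:
  s is slice-sampled, the angle drawn directly;
* the walk scale gets a centered slice update, an
  ancillarity-sufficiency interweaving (non-centered) update, and a
  collapsed Metropolis move under the exact Kalman marginal likelihood
  (states integrated out), which removes the random-walk variance
  funnel; the trial-wise model uses the same collapsed move along its
  (sigma_mu, sigma_y) ridge.

Every update is exact Gibbs, exact slice, or Metropolis-Hastings with a
tractable ratio; there are no step sizes to hand-tune and no
divergences.  Warmup only serves to forget the initialization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from navlearn.io import RunConfig, SamplerConfig, records_to_frame

__all__ = [
    "StateSpacePosterior",
    "ConvergenceReport",
    "ModelBuildError",
    "fit_block_model",
    "fit_trial_model",
    "diagnose",
    "sample_prior_states",
]

_MU1_PRIOR_SD = 1.0
_MISSING_ETA_SCALE = 1.0
_SCALE_FLOOR = 1e-6  # log-degrees; effectively zero noise, keeps densities proper
_LOG_UPPER_DEFAULT = 180.0


class ModelBuildError(ValueError):
    """The trial data cannot support the requested model."""


@dataclass
class StateSpacePosterior:
    """MCMC draws of one fitted state-space model.

    ``mu`` has shape (chains, draws, n_states) on the log-degrees scale:
    one state per block for the block-wise model, one per scheduled
    retrieval trial for the trial-wise model.  ``eta`` (block model only)
    has shape (chains, draws, n_trials) covering every scheduled trial,
    missing ones imputed from their prior.  Scale draws have shape
    (chains, draws).  ``meta`` records the sampler settings and the trial
    layout needed to recompute pointwise likelihoods.
    """

    model: str
    mu: np.ndarray
    eta: np.ndarray | None
    sigma_mu: np.ndarray
    sigma_eta: np.ndarray | None
    sigma_y: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def n_draws(self) -> int:
        """Post-warmup draws per chain."""
        return self.mu.shape[1]

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.n_draws

    @property
    def n_states(self) -> int:
        return self.mu.shape[2]

    def param_dict(self) -> dict[str, np.ndarray | None]:
        return {
            "mu": self.mu,
            "eta": self.eta,
            "sigma_mu": self.sigma_mu,
            "sigma_eta": self.sigma_eta,
            "sigma_y": self.sigma_y,
        }

    def state_draws_deg(self) -> np.ndarray:
        """exp(mu) pooled over chains, shape (total_draws, n_states)."""
        return np.exp(self.mu.reshape(-1, self.n_states))


@dataclass
class ConvergenceReport:
    rhat: pd.Series
    ess: pd.Series
    passed: bool
    rhat_threshold: float
    ess_threshold: float

    @property
    def max_rhat(self) -> float:
        return float(self.rhat.max())

    @property
    def min_ess(self) -> float:
        return float(self.ess.min())


# ---------------------------------------------------------------------------
# sampling primitives
# ---------------------------------------------------------------------------


def _slice_sample(x0: float, logpdf, rng: np.random.Generator,
                  w: float = 1.0, max_steps: int = 50) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    lp0 = logpdf(x0)
    logy = lp0 + math.log(rng.random() + 1e-300)
    u = rng.random()
    left = x0 - w * u
    right = left + w
    j = int(rng.integers(0, max_steps))
    k = max_steps - 1 - j
    while j > 0 and logpdf(left) > logy:
        left -= w
        j -= 1
    while k > 0 and logpdf(right) > logy:
        right += w
        k -= 1
    for _ in range(1000):  # guaranteed to accept; cap is a safety valve
        x1 = rng.uniform(left, right)
        if logpdf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def _ffbs(rng: np.random.Generator, m0: float, v0: float, q: float,
          obs_mean: np.ndarray, obs_var: np.ndarray,
          has_obs: np.ndarray) -> np.ndarray:
    """Joint draw of a Gaussian random-walk state chain by FFBS.

    m0/v0: prior mean/variance of the first state; q: innovation
    variance; obs_mean/obs_var: per-state Gaussian pseudo-observations,
    skipped where has_obs is False.
    """
    n = len(obs_mean)
    filt_mean = np.empty(n)
    filt_var = np.empty(n)
    pred_mean, pred_var = m0, v0
    for t in range(n):
        if t > 0:
            pred_mean, pred_var = filt_mean[t - 1], filt_var[t - 1] + q
        if has_obs[t]:
            gain = pred_var / (pred_var + obs_var[t])
            filt_mean[t] = pred_mean + gain * (obs_mean[t] - pred_mean)
            filt_var[t] = pred_var * (1.0 - gain)
        else:
            filt_mean[t], filt_var[t] = pred_mean, pred_var
    x = np.empty(n)
    x[-1] = rng.normal(filt_mean[-1], math.sqrt(filt_var[-1]))
    for t in range(n - 2, -1, -1):
        var = 1.0 / (1.0 / filt_var[t] + 1.0 / q)
        mean = var * (filt_mean[t] / filt_var[t] + x[t + 1] / q)
        x[t] = rng.normal(mean, math.sqrt(var))
    return x


def _rw_marginal_loglik(m0: float, v0: float, q: float, obs: np.ndarray,
                        obs_var, has_obs: np.ndarray) -> float:
    """Marginal log-likelihood of a Gaussian random walk (states integrated
    out) by the Kalman prediction-error decomposition; truncation
    normalizers are handled separately by the caller.  ``obs_var`` may be
    a scalar or a per-observation array."""
    obs_var = np.broadcast_to(np.asarray(obs_var, float), np.shape(obs))
    ll = 0.0
    pred_mean, pred_var = m0, v0
    for t in range(len(obs)):
        if t > 0:
            pred_var += q
        if has_obs[t]:
            s = pred_var + obs_var[t]
            resid = obs[t] - pred_mean
            ll += -0.5 * (math.log(2.0 * math.pi * s) + resid * resid / s)
            gain = pred_var / s
            pred_mean += gain * resid
            pred_var *= 1.0 - gain
    return ll


def _make_scale_logpdf(n: float, ss: float):
    """Log conditional of x = log(sigma) for n Gaussian terms with summed
    squared residuals ss, under a HalfNormal(0, 1) prior on sigma
    (includes the log|d sigma/dx| Jacobian)."""

    def logpdf(x: float) -> float:
        if x > 8.0 or x < -30.0:
            return -np.inf
        s2 = math.exp(2.0 * x)
        return -n * x - 0.5 * ss / s2 - 0.5 * s2 + x

    return logpdf


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def _prepare_trials(trials, chance_level: float,
                    missing_block_fallback: bool) -> dict:
    """Extract and order one subject's retrieval trials for fitting."""
    if not isinstance(trials, pd.DataFrame):
        trials = records_to_frame(trials)
    retrieval = trials[trials["trial_kind"] == "retrieval"].copy()
    if retrieval.empty:
        raise ModelBuildError("no retrieval trials to fit")
    subjects = retrieval["subject_id"].unique()
    if len(subjects) > 1:
        raise ModelBuildError(
            f"fit one subject at a time, got {len(subjects)} subjects"
        )
    retrieval = retrieval.sort_values(
        ["block", "trial_in_block"], kind="stable"
    ).reset_index(drop=True)
    blocks = retrieval["block"].to_numpy(int)
    n_blocks = int(blocks.max())
    observed = ~retrieval["missing"].to_numpy(bool)
    y = retrieval["abs_error"].to_numpy(float)
    if np.any(observed & ~np.isfinite(y)):
        raise ModelBuildError("observed trial with non-finite abs_error")
    n_obs_per_block = np.bincount(blocks[observed] - 1, minlength=n_blocks)
    if (n_obs_per_block > 0).sum() < 2:
        raise ModelBuildError("need >= 1 observed trial in >= 2 blocks")

    # log block means anchor the prior imputation of missing trials
    block_log_mean = np.full(n_blocks, np.nan)
    for b in range(n_blocks):
        mask = observed & (blocks == b + 1)
        if mask.any():
            block_log_mean[b] = math.log(max(y[mask].mean(), 1e-6))
    if np.isnan(block_log_mean).any():
        empty = np.flatnonzero(np.isnan(block_log_mean)) + 1
        if not missing_block_fallback:
            raise ModelBuildError(
                f"block(s) {empty.tolist()} have no observed trials so their "
                "mean is undefined; pass missing_block_fallback=True to anchor "
                "their missing-trial prior at the nearest observed block mean"
            )
        obs_blocks = np.flatnonzero(~np.isnan(block_log_mean))
        for b in np.flatnonzero(np.isnan(block_log_mean)):
            nearest = obs_blocks[np.argmin(np.abs(obs_blocks - b))]
            block_log_mean[b] = block_log_mean[nearest]

    return {
        "subject_id": str(subjects[0]),
        "blocks": blocks,
        "n_blocks": n_blocks,
        "observed": observed,
        "log_y": np.where(observed, np.log(np.maximum(y, 1e-6)), np.nan),
        "block_log_mean": block_log_mean,
        "m0": math.log(chance_level),
    }


def _resolve_config(config) -> tuple[SamplerConfig, float]:
    if isinstance(config, RunConfig):
        config.validate()
        return config.sampler, config.chance_level
    if isinstance(config, SamplerConfig):
        config.validate()
        return config, 90.0
    raise TypeError("config must be a RunConfig or SamplerConfig")


def _base_meta(prep: dict, sampler: SamplerConfig, chance_level: float,
               truncation: float | None) -> dict:
    observed = prep["observed"]
    return {
        "subject_id": prep["subject_id"],
        "seed": int(sampler.seed),
        "iterations": sampler.iterations,
        "warmup": sampler.warmup,
        "chance_level": chance_level,
        "truncation": truncation,
        "n_blocks": prep["n_blocks"],
        "block_of_trial": prep["blocks"].tolist(),
        "observed": observed.tolist(),
        "log_y": [None if not o else float(v)
                  for o, v in zip(observed, prep["log_y"])],
    }


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_block_model(trials, config: RunConfig | SamplerConfig,
                    missing_block_fallback: bool = False,
                    truncation: float | None = _LOG_UPPER_DEFAULT,
                    ) -> StateSpacePosterior:
    """Fit the block-wise state-space model to one subject's trials.

    ``trials`` may be a canonical DataFrame or a sequence of
    :class:`~navlearn.io.TrialRecord`; only retrieval trials enter the
    model.  ``truncation`` is the upper observation bound in degrees
    (``None`` for an untruncated lognormal).  Returns all post-warmup
    draws from every chain.
    """
    sampler, chance_level = _resolve_config(config)
    prep = _prepare_trials(trials, chance_level, missing_block_fallback)
    blocks, observed = prep["blocks"], prep["observed"]
    n_blocks, n_trials = prep["n_blocks"], len(blocks)
    log_y_obs = prep["log_y"][observed]
    block_of_obs = blocks[observed] - 1
    n_obs = int(observed.sum())
    n_obs_per_block = np.bincount(block_of_obs, minlength=n_blocks).astype(float)
    has_obs = n_obs_per_block > 0
    n_b = np.maximum(n_obs_per_block, 1.0)
    miss_loc = prep["block_log_mean"][blocks[~observed] - 1]
    m0 = prep["m0"]
    u = math.log(truncation) if truncation is not None else None

    n_keep = sampler.draws_per_chain
    mu_out = np.empty((sampler.chains, n_keep, n_blocks))
    eta_out = np.empty((sampler.chains, n_keep, n_trials))
    sm_out = np.empty((sampler.chains, n_keep))
    se_out = np.empty((sampler.chains, n_keep))
    sy_out = np.empty((sampler.chains, n_keep))

    # per-block mean of log errors: with eta collapsed, marginally each
    # observed log y_t ~ Normal(mu_b, s^2)/Phi((u - mu_b)/s), so the block
    # means are the sufficient statistics for mu and the truncation
    # normalizers depend only on (mu_b, s)
    logy_bar = np.zeros(n_blocks)
    np.add.at(logy_bar, block_of_obs, log_y_obs)
    logy_bar = np.where(has_obs, logy_bar / n_b, 0.0)
    n_blocks_obs = int(has_obs.sum())
    ss_within = float(np.sum((log_y_obs - logy_bar[block_of_obs]) ** 2))

    def block_corr(mu_vec: np.ndarray, s: float) -> float:
        """Summed log normalizers n_b * log Phi((u - mu_b)/s)."""
        if u is None:
            return 0.0
        return float(np.sum(n_obs_per_block * log_ndtr((u - mu_vec) / s)))

    def tilt_shift(s: float) -> np.ndarray:
        """First-order tilt of the block pseudo-observations toward the
        truncation correction, expanded at the fixed block means: the
        inverse-Mills hazard lambda((u - logy_bar_b)/s) times s.  Proposals
        drawn under this fixed linear tilt are independence proposals, so
        their normalizers cancel in the acceptance ratio."""
        z = (u - logy_bar) / s
        lam = np.exp(-0.5 * z**2 - 0.5 * math.log(2.0 * math.pi) - log_ndtr(z))
        return np.where(has_obs, lam * s, 0.0)

    def tilted_log_alpha(mu_new: np.ndarray, mu_old: np.ndarray, s: float,
                         shift: np.ndarray) -> float:
        """MH remainder for proposals drawn under the linear tilt
        G(mu) = sum_b n_b (shift_b/s^2) mu_b (second-order only)."""
        g = n_obs_per_block * shift / s**2
        return (block_corr(mu_old, s) - block_corr(mu_new, s)
                + float(np.sum(g * (mu_old - mu_new))))

    n_keep = sampler.draws_per_chain
    mu_out = np.empty((sampler.chains, n_keep, n_blocks))
    eta_out = np.empty((sampler.chains, n_keep, n_trials))
    sm_out = np.empty((sampler.chains, n_keep))
    se_out = np.empty((sampler.chains, n_keep))
    sy_out = np.empty((sampler.chains, n_keep))

    seeds = np.random.SeedSequence([int(sampler.seed), 17]).spawn(sampler.chains)
    for c in range(sampler.chains):
        rng = np.random.default_rng(seeds[c])
        mu = prep["block_log_mean"].copy() + rng.normal(0, 0.1, n_blocks)
        sigma_mu = math.exp(rng.normal(-1.0, 0.3))
        sigma_eta = math.exp(rng.normal(-1.0, 0.3))
        sigma_y = math.exp(rng.normal(-1.0, 0.3))
        eta_full = np.empty(n_trials)
        for it in range(sampler.iterations):
            s2 = sigma_eta**2 + sigma_y**2
            s_tot = math.sqrt(s2)
            # mu | scales, y (eta collapsed): FFBS under the unbounded model
            # with the block observations shifted by the first-order tilt of
            # the truncation normalizers (independence proposal); accepted
            # with the second-order remainder, which is near 1
            def tilted_stats(s: float):
                """Tilt shift, effective observations, tilt gradient and the
                mu-free log constant K(s) of the tilted re-completion."""
                if u is None:
                    zero = np.zeros(n_blocks)
                    return zero, logy_bar, zero, 0.0
                sh = tilt_shift(s)
                g = n_obs_per_block * sh / s**2
                v = s**2 / n_b
                log_k = float(np.sum(np.where(
                    has_obs, g * logy_bar + 0.5 * g**2 * v, 0.0)))
                return sh, logy_bar + sh, g, log_k

            shift, obs_eff, g_tilt, log_k = tilted_stats(s_tot)

            # collapsed Metropolis move for the total scale s (mu integrated
            # out under the tilted base): lets chains hop between the
            # low-noise and heavy-truncation explanations of near-chance data
            s_p = s_tot * math.exp(rng.normal(0.0, 0.5))
            if _SCALE_FLOOR < s_p < 1e3:
                sh_p, obs_p, g_p, log_k_p = tilted_stats(s_p)

                def s_lp(s_val, obs_v, log_k_v):
                    # Rayleigh prior on s (polar radius of two half-normals)
                    # + Kalman marginal of the block means + the within-block
                    # scatter factor of the Gaussian likelihood + tilt const
                    return (2.0 * math.log(s_val) - 0.5 * s_val**2
                            + _rw_marginal_loglik(
                                m0, _MU1_PRIOR_SD**2, sigma_mu**2,
                                obs_v, s_val**2 / n_b, has_obs)
                            - (n_obs - n_blocks_obs) * math.log(s_val)
                            - 0.5 * ss_within / s_val**2
                            + log_k_v)

                lp_new = s_lp(s_p, obs_p, log_k_p)
                lp_old = s_lp(s_tot, obs_eff, log_k)
                mu_p = _ffbs(rng, m0, _MU1_PRIOR_SD**2, sigma_mu**2,
                             obs_p, s_p**2 / n_b, has_obs)
                log_alpha = lp_new - lp_old
                if u is not None:
                    log_alpha += (-block_corr(mu_p, s_p)
                                  - float(np.sum(g_p * mu_p))
                                  + block_corr(mu, s_tot)
                                  + float(np.sum(g_tilt * mu)))
                if math.log(rng.random() + 1e-300) < log_alpha:
                    theta_cur = math.atan2(sigma_y, sigma_eta)
                    s_tot, mu = s_p, mu_p
                    s2 = s_p**2
                    sigma_eta = max(s_p * math.cos(theta_cur), _SCALE_FLOOR)
                    sigma_y = max(s_p * math.sin(theta_cur), _SCALE_FLOOR)
                    shift, obs_eff, g_tilt, log_k = sh_p, obs_p, g_p, log_k_p
            # collapsed Metropolis move for sigma_mu (mu integrated out under
            # the tilted base via the Kalman marginal), with a joint FFBS
            # redraw of mu; kills the walk-scale funnel for flat subjects
            sm_p = sigma_mu * math.exp(rng.normal(0.0, 0.6))
            if _SCALE_FLOOR < sm_p < 1e3:
                lp_cur = (_rw_marginal_loglik(m0, _MU1_PRIOR_SD**2, sigma_mu**2,
                                              obs_eff, s2 / n_b, has_obs)
                          - 0.5 * sigma_mu**2 + math.log(sigma_mu))
                lp_prop = (_rw_marginal_loglik(m0, _MU1_PRIOR_SD**2, sm_p**2,
                                               obs_eff, s2 / n_b, has_obs)
                           - 0.5 * sm_p**2 + math.log(sm_p))
                mu_p = _ffbs(rng, m0, _MU1_PRIOR_SD**2, sm_p**2,
                             obs_eff, s2 / n_b, has_obs)
                log_alpha = lp_prop - lp_cur
                if u is not None:
                    log_alpha += (tilted_log_alpha(mu_p, mu, s_tot, shift))
                if math.log(rng.random() + 1e-300) < log_alpha:
                    sigma_mu, mu = sm_p, mu_p
            # mu | scales, y (eta collapsed): FFBS under the unbounded model
            # with the block observations shifted by the first-order tilt of
            # the truncation normalizers (independence proposal); accepted
            # with the second-order remainder, which is near 1
            mu_p = _ffbs(rng, m0, _MU1_PRIOR_SD**2, sigma_mu**2,
                         obs_eff, s2 / n_b, has_obs)
            if u is None:
                mu = mu_p
            elif math.log(rng.random() + 1e-300) < tilted_log_alpha(
                    mu_p, mu, s_tot, shift):
                mu = mu_p
            # sigma_mu: centered slice (exact; normalizers are mu/s only) ...
            ss_mu = max(float(np.sum(np.diff(mu) ** 2)), 1e-12)
            sigma_mu = max(math.exp(_slice_sample(
                math.log(sigma_mu), _make_scale_logpdf(n_blocks - 1, ss_mu), rng)),
                _SCALE_FLOOR)
            # ... then interweaved non-centered update: mu_b = b0 + beta c_b
            # with innovations held fixed; (b0, beta) drawn from their
            # conjugate conditional under the unbounded collapsed model and
            # accepted with the truncation-normalizer ratio (mu moves)
            cvec = np.concatenate([[0.0], np.cumsum(np.diff(mu))]) / sigma_mu
            w = n_obs_per_block / s2
            b0 = mu[0]
            prec_b = 1.0 + float(np.sum(w * cvec**2))
            mean_b = float(np.sum(w * cvec * (obs_eff - b0))) / prec_b
            beta = mean_b + math.sqrt(1.0 / prec_b) * rng.standard_normal()
            prec_0 = 1.0 / _MU1_PRIOR_SD**2 + float(np.sum(w))
            mean_0 = (m0 / _MU1_PRIOR_SD**2
                      + float(np.sum(w * (obs_eff - beta * cvec)))) / prec_0
            b0_new = mean_0 + math.sqrt(1.0 / prec_0) * rng.standard_normal()
            if math.isfinite(beta) and math.isfinite(b0_new):
                mu_p = b0_new + beta * cvec
                if u is None:
                    accept_iw = True
                else:
                    accept_iw = math.log(rng.random() + 1e-300) < \
                        tilted_log_alpha(mu_p, mu, s_tot, shift)
                if accept_iw:
                    mu = mu_p
                    sigma_mu = min(max(abs(beta), _SCALE_FLOOR), 1e3)
            # scale split | mu, y (eta collapsed): the likelihood and the
            # normalizers identify only s; the polar angle between sigma_eta
            # and sigma_y is exactly Uniform(0, pi/2) under the half-normal
            # priors, so s is slice-sampled and the angle drawn directly
            ss_marg = max(float(np.sum((log_y_obs - mu[block_of_obs]) ** 2)), 1e-12)

            def lp_s(x: float) -> float:
                if x > 8.0 or x < -30.0:
                    return -np.inf
                e2x = math.exp(2.0 * x)
                lp = (2.0 - n_obs) * x - 0.5 * ss_marg / e2x - 0.5 * e2x
                if u is not None:
                    lp -= block_corr(mu, math.exp(x))
                return lp

            s_tot = max(math.exp(_slice_sample(
                math.log(s_tot), lp_s, rng)), _SCALE_FLOOR)
            theta = rng.uniform(0.0, 0.5 * math.pi)
            sigma_eta = max(s_tot * math.cos(theta), _SCALE_FLOOR)
            sigma_y = max(s_tot * math.sin(theta), _SCALE_FLOOR)
            if it >= sampler.warmup:
                k = it - sampler.warmup
                # eta | mu, scales, y: exact Gaussian conditional (truncation
                # conditions on the observed y, which is fixed here); missing
                # trials are prior imputation with no likelihood term
                var = 1.0 / (1.0 / sigma_eta**2 + 1.0 / sigma_y**2)
                mean = (mu[block_of_obs] / sigma_eta**2
                        + log_y_obs / sigma_y**2) * var
                eta_full[observed] = mean + math.sqrt(var) * rng.standard_normal(n_obs)
                if n_trials > n_obs:
                    eta_full[~observed] = miss_loc + np.abs(
                        rng.normal(0.0, _MISSING_ETA_SCALE, n_trials - n_obs))
                mu_out[c, k] = mu
                eta_out[c, k] = eta_full
                sm_out[c, k] = sigma_mu
                se_out[c, k] = sigma_eta
                sy_out[c, k] = sigma_y

    return StateSpacePosterior(
        model="block", mu=mu_out, eta=eta_out,
        sigma_mu=sm_out, sigma_eta=se_out, sigma_y=sy_out,
        meta=_base_meta(prep, sampler, chance_level, truncation),
    )


def fit_trial_model(trials, config: RunConfig | SamplerConfig,
                    missing_block_fallback: bool = False,
                    truncation: float | None = _LOG_UPPER_DEFAULT,
                    ) -> StateSpacePosterior:
    """Fit the trial-wise alternative (state walks from trial to trial).

    The intermediate eta layer is absent; missing trials keep a latent
    state (the walk passes through them) but contribute no likelihood.
    """
    sampler, chance_level = _resolve_config(config)
    prep = _prepare_trials(trials, chance_level, missing_block_fallback)
    blocks, observed = prep["blocks"], prep["observed"]
    n_trials = len(blocks)
    log_y = prep["log_y"]
    log_y_obs = log_y[observed]
    n_obs = int(observed.sum())
    m0 = prep["m0"]
    u = math.log(truncation) if truncation is not None else None

    def corr_sum(mu_obs: np.ndarray, sigma: float) -> float:
        """Summed log CDF normalizers over observed trials."""
        if u is None:
            return 0.0
        return float(np.sum(log_ndtr((u - mu_obs) / sigma)))

    n_keep = sampler.draws_per_chain
    mu_out = np.empty((sampler.chains, n_keep, n_trials))
    sm_out = np.empty((sampler.chains, n_keep))
    sy_out = np.empty((sampler.chains, n_keep))

    obs_mean = np.where(observed, np.nan_to_num(log_y), 0.0)
    obs_var = np.empty(n_trials)
    seeds = np.random.SeedSequence([int(sampler.seed), 23]).spawn(sampler.chains)
    for c in range(sampler.chains):
        rng = np.random.default_rng(seeds[c])
        mu = prep["block_log_mean"][blocks - 1] + rng.normal(0, 0.1, n_trials)
        sigma_mu = math.exp(rng.normal(-1.5, 0.3))
        sigma_y = math.exp(rng.normal(-1.0, 0.3))
        lp_marg = None
        for it in range(sampler.iterations):
            # collapsed Metropolis move along the sigma_mu/sigma_y ridge:
            # propose scales under the exact Kalman marginal (states out),
            # redraw the state path, accept jointly with truncation terms
            if lp_marg is None:
                lp_marg = (_rw_marginal_loglik(m0, _MU1_PRIOR_SD**2, sigma_mu**2,
                                               obs_mean, sigma_y**2, observed)
                           - 0.5 * sigma_mu**2 - 0.5 * sigma_y**2
                           + math.log(sigma_mu) + math.log(sigma_y))
            d = rng.normal(0.0, 0.15)
            eps = rng.normal(0.0, 0.05, 2)
            sm_p = sigma_mu * math.exp(d + eps[0])
            sy_p = sigma_y * math.exp(-d + eps[1])
            if _SCALE_FLOOR < sm_p < 1e3 and _SCALE_FLOOR < sy_p < 1e3:
                lp_prop = (_rw_marginal_loglik(m0, _MU1_PRIOR_SD**2, sm_p**2,
                                               obs_mean, sy_p**2, observed)
                           - 0.5 * sm_p**2 - 0.5 * sy_p**2
                           + math.log(sm_p) + math.log(sy_p))
                obs_var[:] = sy_p**2
                mu_p = _ffbs(rng, m0, _MU1_PRIOR_SD**2, sm_p**2,
                             obs_mean, obs_var, observed)
                log_alpha = (lp_prop - lp_marg
                             - corr_sum(mu_p[observed], sy_p)
                             + corr_sum(mu[observed], sigma_y))
                if math.log(rng.random() + 1e-300) < log_alpha:
                    sigma_mu, sigma_y, mu, lp_marg = sm_p, sy_p, mu_p, lp_prop
            # mu refresh: FFBS under the unbounded model as independence
            # proposal, accepted with the truncation-normalizer ratio
            obs_var[:] = sigma_y**2
            mu_p = _ffbs(rng, m0, _MU1_PRIOR_SD**2, sigma_mu**2,
                         obs_mean, obs_var, observed)
            log_alpha = (corr_sum(mu[observed], sigma_y)
                         - corr_sum(mu_p[observed], sigma_y))
            if math.log(rng.random() + 1e-300) < log_alpha:
                mu = mu_p
            # sigma_mu: centered slice (exact), then interweaved update
            # accepted with the truncation ratio (it moves mu)
            ss_mu = max(float(np.sum(np.diff(mu) ** 2)), 1e-12)
            sigma_mu = max(math.exp(_slice_sample(
                math.log(sigma_mu), _make_scale_logpdf(n_trials - 1, ss_mu), rng)),
                _SCALE_FLOOR)
            cvec = np.concatenate([[0.0], np.cumsum(np.diff(mu))]) / sigma_mu
            c_obs = cvec[observed]
            b0 = mu[0]
            prec_b = 1.0 + float(np.sum(c_obs**2)) / sigma_y**2
            mean_b = float(np.sum(c_obs * (log_y_obs - b0))) / sigma_y**2 / prec_b
            beta = mean_b + math.sqrt(1.0 / prec_b) * rng.standard_normal()
            prec_0 = 1.0 / _MU1_PRIOR_SD**2 + n_obs / sigma_y**2
            mean_0 = (m0 / _MU1_PRIOR_SD**2
                      + float(np.sum(log_y_obs - beta * c_obs)) / sigma_y**2) / prec_0
            b0_new = mean_0 + math.sqrt(1.0 / prec_0) * rng.standard_normal()
            if math.isfinite(beta) and math.isfinite(b0_new):
                mu_p = b0_new + beta * cvec
                log_alpha = (corr_sum(mu[observed], sigma_y)
                             - corr_sum(mu_p[observed], sigma_y))
                if math.log(rng.random() + 1e-300) < log_alpha:
                    mu = mu_p
                    sigma_mu = min(max(abs(beta), _SCALE_FLOOR), 1e3)
            # sigma_y | mu, y (with truncation normalizers)
            ss_y = max(float(np.sum((log_y_obs - mu[observed]) ** 2)), 1e-12)
            mu_obs_now = mu[observed]

            def lp_sigma_y(x: float) -> float:
                if x > 8.0 or x < -30.0:
                    return -np.inf
                sy = math.exp(x)
                ll = -n_obs * x - 0.5 * ss_y / sy**2
                if u is not None:
                    ll -= float(np.sum(log_ndtr((u - mu_obs_now) / sy)))
                return ll - 0.5 * sy**2 + x

            sigma_y = max(math.exp(_slice_sample(
                math.log(sigma_y), lp_sigma_y, rng)), _SCALE_FLOOR)
            lp_marg = None  # scales changed; marginal must be recomputed
            if it >= sampler.warmup:
                k = it - sampler.warmup
                mu_out[c, k] = mu
                sm_out[c, k] = sigma_mu
                sy_out[c, k] = sigma_y

    return StateSpacePosterior(
        model="trial", mu=mu_out, eta=None,
        sigma_mu=sm_out, sigma_eta=None, sigma_y=sy_out,
        meta=_base_meta(prep, sampler, chance_level, truncation),
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def _to_arviz(posterior: StateSpacePosterior):
    import arviz as az

    data = {"mu": posterior.mu, "sigma_mu": posterior.sigma_mu,
            "sigma_y": posterior.sigma_y}
    if posterior.eta is not None:
        data["eta"] = posterior.eta
    if posterior.sigma_eta is not None:
        data["sigma_eta"] = posterior.sigma_eta
    return az.from_dict(posterior=data)


def _flatten_dataset(ds) -> pd.Series:
    out = {}
    for name, da in ds.items():
        vals = np.atleast_1d(da.values)
        if vals.ndim == 0 or vals.size == 1:
            out[name] = float(vals.reshape(-1)[0])
        else:
            for i, v in enumerate(vals.reshape(-1)):
                out[f"{name}[{i + 1}]"] = float(v)
    return pd.Series(out)


def diagnose(posterior: StateSpacePosterior,
             rhat_threshold: float = 1.05,
             ess_threshold: float = 400.0) -> ConvergenceReport:
    """Convergence check: rank-normalized split-Rhat and bulk ESS.

    Passes iff max Rhat <= ``rhat_threshold`` and min bulk ESS >=
    ``ess_threshold`` across all parameters.  Requires >= 2 chains (Rhat
    is undefined for a single chain).
    """
    import arviz as az

    if posterior.n_chains < 2:
        raise ValueError("Rhat requires at least 2 chains")
    idata = _to_arviz(posterior)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = _flatten_dataset(az.rhat(idata))
        ess = _flatten_dataset(az.ess(idata, method="bulk"))
    passed = bool(rhat.max() <= rhat_threshold and ess.min() >= ess_threshold)
    return ConvergenceReport(rhat=rhat, ess=ess, passed=passed,
                             rhat_threshold=rhat_threshold,
                             ess_threshold=ess_threshold)


def sample_prior_states(n_draws: int, n_blocks: int = 8,
                        chance_level: float = 90.0,
                        seed: int = 0) -> np.ndarray:
    """Draws of exp(mu) from the prior alone (no data), shape (n_draws, B).

    Useful as a prior-predictive sanity check: with no data the first
    state centers at chance level.
    """
    rng = np.random.default_rng(seed)
    sigma_mu = np.abs(rng.normal(0.0, 1.0, n_draws))
    mu = np.empty((n_draws, n_blocks))
    mu[:, 0] = rng.normal(math.log(chance_level), _MU1_PRIOR_SD, n_draws)
    for b in range(1, n_blocks):
        mu[:, b] = mu[:, b - 1] + rng.normal(0.0, 1.0, n_draws) * sigma_mu
    return np.exp(mu)
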