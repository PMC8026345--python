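# navlearn

Bayesian analysis of spatial-learning dynamics from pointing-error data.

In landmark-pointing experiments, subjects repeatedly point toward
unseen landmarks across eight learning blocks; the absolute angular
error (0–180°, with 90° the chance level of uniform random pointing)
measures how well the environment's layout has been learned.  Raw
errors are noisy, so the quantity of interest is latent: `navlearn`
estimates each subject's hidden per-block learning state with a
hierarchical Bayesian state-space model and builds the downstream
analyses on the posterior.  It is a library for researchers studying
spatial learning and cognitive aging who want the full chain — latent
state estimation, model criticism, derived learning metrics, learner
subtyping, and age-group classification — reproducible end to end.

## The model

For one subject with trial outcomes `y_t` (absolute error in degrees):

    mu_1   ~ Normal(log 90, 1)                       first block near chance
    mu_b   ~ Normal(mu_{b-1}, sigma_mu)              random-walk learning state
    eta_t  ~ Normal(mu_{b(t)}, sigma_eta)            trial effects, shrunk to block
    y_t    ~ LogNormal(eta_t, sigma_y), y_t <= 180   bounded pointing error
    eta_t  ~ log(mean_b y) + |Normal(0, 1)|          timeouts: prior imputation

`exp(mu_b)` is the learning state in degrees.  A trial-wise alternative
(no `eta`, state walks per trial) serves as the PSIS-LOO comparison
baseline.  Inference is by an exact structured MCMC sampler
(forward-filter backward-sampling for the states, collapsed and
interweaved updates for the scales, truncation handled by tractable
Metropolis ratios) — see `docs/methods.md`.

On top of the model the package derives learning curves, the per-block
amount of learning `L_b` (block 1 referenced to the 90° chance level;
`sum(L) = 90 − final state` by construction) and its mean, normalized
fMRI contrast weights, and per-subject difference features (mean and SD
of the posterior first-minus-last state difference).  Subjects are
clustered into learner subgroups by silhouette-selected K-means on
those features; a nested cross-validated logistic regression classifies
age group from the mean amount of learning and the block-4-to-5
response-time change; and a Watson-Williams screen checks signed errors
for directional biases per design cell.  A synthetic-cohort generator
with five learner archetypes (top, good, intermediate, weak,
non-learner) and known ground truth makes every stage testable.

## Worked example

`examples/fit_single_subject.py` simulates a "good learner" (96 trials,
8 blocks), fits the block-wise model and prints the estimated learning
curve next to the planted truth:

```
convergence: max Rhat = 1.005, min bulk ESS = 1485 (2000 post-warmup draws)

block   planted   estimated (posterior mean +- SD)
  1       60.0      57.9 +-  4.8
  2       55.0      55.5 +-  4.6
  3       45.5      42.8 +-  3.5
  4       38.9      40.0 +-  3.4
  5       31.3      29.7 +-  2.4
  6       23.9      26.0 +-  2.2
  7       16.7      16.1 +-  1.4
  8        7.6       7.8 +-  0.7
```

The subject starts below chance (90°) because some learning already
happened during familiarization, and the posterior tracks the planted
state within its uncertainty as the error falls to single digits.  The
other examples cover cohort simulation, model comparison
(`loo_compare`), learner subtyping (`cluster_learners`), age-group
classification (`classify_age`) and the circular bias screen
(`bias_screen`).  A thin CLI wraps the same functions:
`navlearn simulate | fit | evaluate | metrics | cluster | classify |
bias | run`.

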