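# Methods

## The behavioral task and its data

Subjects learn the layout of a small virtual city across eight learning
blocks.  In every retrieval trial they are driven to one of four
intersections from one of four directions and rotate a crosshair toward
one of two target landmarks.  The outcome is the absolute pointing
error in degrees: the angular deviation between response and true
target direction, bounded by 180°.  Under uniform random pointing the
signed error is uniform on (−180°, 180°], so the expected absolute
error — the chance level — is exactly 90°.

Two session layouts are supported.  The behavioral layout has 8 blocks
of 12 retrieval trials (4 intersections × 4 directions × 2 targets × 3
repetitions = 96 trials), with the extra constraint that each
intersection/target pair is approached from two of the four directions
in the first half of the session and from the other two in the second
half.  The fMRI layout has 8 blocks of 8 retrieval trials (2
repetitions, 64 trials) plus 4 color-judgment control trials per block
(32 trials) and no direction change.  Trials can be missing (12-s
timeout); missing trials are kept as rows because the model needs their
position in the schedule.

## The state-space model

Raw pointing errors are noisy; the quantity of scientific interest is a
latent per-block performance level.  The block-wise model is a local
level model on the log scale with an intermediate trial-effect layer:

    mu_1   ~ Normal(log(90), 1)
    mu_b   ~ Normal(mu_{b-1}, sigma_mu)            b = 2..8
    eta_t  ~ Normal(mu_{b(t)}, sigma_eta)          observed trials
    y_t    ~ LogNormal(eta_t, sigma_y)  conditioned on y_t <= 180
    sigma_mu, sigma_eta, sigma_y ~ HalfNormal(0, 1)

`exp(mu_b)` is the hidden learning state in degrees.  The trial effects
eta shrink single trials toward their block's state: performance is
expected to change between encoding phases, not from trial to trial.
Missing trials contribute no likelihood; their eta is imputed from a
half-normal prior located at the log of the observed block mean, so a
timeout is treated as "at least as poor as the block average" without
inventing an outcome.  The trial-wise alternative drops eta and lets
the state itself walk from trial to trial; comparing the two by
PSIS-LOO asks whether the block structure earns its keep.

Model choices worth spelling out:

* **Log scale.**  Errors are positive and right-skewed, and the
  missing-trial prior is naturally located at a log mean; a lognormal
  observation family follows.
* **Truncation at 180°.**  An absolute pointing error cannot exceed
  180°.  For subjects near chance with realistic noise (log-SD ≈ 0.5),
  more than 10% of an untruncated lognormal's mass would lie beyond the
  bound; ignoring this biases near-chance states downward by ~10%, which
  parameter-recovery runs make clearly visible.  The model therefore
  conditions each outcome on the bound (marginally, log y is a normal
  truncated at log 180).  A consequence worth knowing: for a subject at
  chance the data cannot distinguish "state 90, moderate noise" from
  "state far above 90, large noise, heavily truncated", so near-chance
  posteriors are wide and right-skewed.  That uncertainty is real, not
  an artifact.
* **Weakly informative priors.**  The first state is centered at chance
  with SD 1 on the log scale (a factor of e in either direction);
  half-normal(0,1) on all scales.  The split between sigma_eta and
  sigma_y is identified only by these priors (the collapsed likelihood
  sees just their sum of squares); downstream quantities depend on the
  total scale, not the split.

## Posterior computation

Conditioned on the scales the model is linear-Gaussian in (mu, eta), and
the truncated likelihood differs from the Gaussian one only through
normal-CDF normalizers.  The sampler is a structured
Metropolis-within-Gibbs scheme that exploits this:

* eta is integrated out analytically for all state and scale updates and
  re-drawn from its exact Gaussian conditional when a draw is recorded;
* the state chain is proposed jointly by forward-filtering
  backward-sampling under a first-order exponential tilt of the CDF
  normalizers (expansion point: the observed block means) and accepted
  with the second-order remainder — acceptance is near 1;
* the total noise scale s = sqrt(sigma_eta² + sigma_y²) is updated by
  slice sampling (conditionally on the states) and by a collapsed
  Metropolis move with the states integrated out via the Kalman
  prediction-error decomposition; the polar angle between sigma_eta and
  sigma_y is exactly uniform under the half-normal priors and is drawn
  directly;
* the walk scale sigma_mu gets a centered slice update, an
  ancillarity-sufficiency interweaving (non-centered) update, and its
  own collapsed Kalman-marginal Metropolis move.  The combination
  removes the random-walk variance funnel that makes naive Gibbs
  samplers of local level models mix poorly.

The trial-wise model uses the same toolbox (FFBS proposals with
truncation-ratio acceptance, collapsed scale moves).  There are no
step-size parameters and no divergences; warmup only forgets the
initialization.  Convergence is checked with rank-normalized split-Rhat
and bulk ESS (thresholds 1.05 and 400; the published analyses only
state that convergence was checked, so the thresholds are this
package's choice).  Correctness of the sampler is tested against a
deliberately naive random-walk Metropolis run on the same collapsed
posterior; during development it was also cross-checked against JAGS,
which agreed on the posterior bulk but under-explored the heavy
near-chance right tail.

Default sampler settings: 4 chains × 1000 iterations (500 warmup) for
desk-scale work; the published configuration of 4 chains × 4000
iterations (2000 warmup, 8000 post-warmup draws) is available as a
preset.  One fit takes on the order of a second.

## Model checking and comparison

The posterior predictive check re-simulates every observed trial from
the fitted observation model at each retained draw and reports the
fraction of observed outcomes inside central 95% predictive intervals,
per block and overall.

Model comparison uses Pareto-smoothed importance-sampling LOO with one
observed trial as the pointwise unit (missing trials carry no
likelihood and are excluded).  Two pointwise units are exposed because
they answer different questions:

* `conditioning="local"` (default) conditions the block model on eta —
  the factorization a Stan generated-quantities `log_lik` would use.
  It is the *sensitive* unit: the shrinkage layer adapts to every
  outcome, and on data with block structure it rewards the hierarchical
  model strongly (differences of tens of nats per subject).  Its known
  cost is optimism about per-observation latents: many Pareto-k values
  exceed 0.7 and the comparison is flagged unreliable; the sign is the
  robust part, the magnitude is not.
* `conditioning="state"` integrates eta out and conditions each model
  on its latent state only.  It is the *specific* unit: with no free
  per-observation parameter the sign flips to favor the trial-wise
  model when data really come from a per-trial random walk.

The reported difference is elpd(block) − elpd(trial); positive values
favor the block-wise model.

## Derived metrics

The learning curve is the per-block posterior mean and SD of exp(mu_b).
The amount of learning is L_1 = 90 − curve_1 and
L_b = curve_{b−1} − curve_b for later blocks, crediting learning that
happened before the first retrieval phase (during familiarization) to
block 1.  The telescoping identity sum(L) = 90 − curve_B holds to
numerical precision by construction and is property-tested.  fMRI
contrast weights are the L vector mean-centered and scaled to unit
Euclidean norm ("normalized differences" is otherwise underspecified;
mean-zero unit-norm is the standard convention for parametric contrast
vectors, and the raw L is exported alongside).  A flat curve at chance
yields an explicit all-zero weight vector with a degeneracy flag rather
than an exception.

The clustering features are the mean and SD of the posterior
distribution of exp(mu_1) − exp(mu_8) (first minus last, so positive
means improvement; a maximum-likelihood normal fit to draws is exactly
their sample mean and population SD).  The SD captures judgment
uncertainty, which distinguishes confident non-learners from confident
early learners with equally flat curves.

## Subgrouping and classification

Learner subgroups come from K-means (k-means++ initialization, 50
restarts, fixed seed) on the z-scored two-dimensional feature space,
with the number of clusters selected by the mean silhouette coefficient
over k = 3..7 (ties toward the smaller k).  Labels are reported with
cluster 1 = strongest learners.  Feature standardization is this
package's choice; the two features differ in spread by an order of
magnitude, and K-means without scaling would be dominated by the mean
dimension.

Age-group classification uses an L2-regularized logistic regression on
(mean amount of learning, block-4-to-5 response-time change), evaluated
by nested stratified cross-validation: outer folds give held-out AUCs;
an inner fold loop on each training split selects the regularization
strength from a 13-point grid 10^-3..10^3; z-scoring parameters are fit
on training folds only.  "Nested 10-fold" is interpreted as 10 outer
and up to 10 inner folds, shrunk when a class is too small to stratify.

## Circular statistics

Signed errors are wrapped into (−180°, 180°] via
((response − target + 180) mod 360) − 180.  Per-cell age-group
comparisons use the classical Watson-Williams test with correction
factor K = 1 + 3/(8 kappa), kappa estimated from the pooled within-group
mean resultant length by the standard piecewise inverse-A
approximation, and an F(k−1, N−k) reference distribution.  A validity
warning fires when the pooled resultant length drops below 0.45 or a
group has fewer than five observations.  The 32-cell screen reports raw
and Bonferroni-adjusted decisions (the multiplicity method is this
package's choice; the number of tests is the number of non-empty
cells).

## The synthetic cohort generator

The generator is the package's test bed: it emulates both session
layouts and plants known ground truth.  Each subject follows one of
five learner archetypes (top, good, intermediate, weak, non-learner);
an archetype fixes the initial latent error level, a linear per-block
drift, the SD of random-walk jitter around that trend, the log-scale
trial noise, a timeout probability, and response-time dynamics (linear
decline plus a block-5 bump applied to older subjects under the
direction-split layout).  Observed errors are drawn lognormally around
the latent level and resampled above 180° — the same conditioning the
model assumes.  Default archetype constants are fixed package choices
tuned once so that the archetypes are separable in the
(difference-mean, difference-SD) feature space at realistic noise; the
default mixing proportions mirror the published subgroup composition
(per 57 subjects: 9 top, 14 good, 9 intermediate, 12 weak, 13
non-learners, with good learners all young and weak learners all old).
Seeds expand to per-subject substreams through a counter-based scheme,
so cohorts are reproducible and independent of simulation order.

What the generator does not emulate: serial position and practice
effects within blocks, cell-specific difficulty (some
intersection/direction/target combinations are genuinely harder),
left/right pointing biases, encoding-tour direction, and any
correlation between timeout probability and momentary performance.
Passing recovery and subgroup tests therefore shows the pipeline is
correct and well-calibrated for data of this structure, not that the
model captures every feature of real behavior.

## Problem sizes and numerical choices

Test and acceptance runs use 20 subjects for parameter recovery, 10 for
the model-comparison direction, 20 simulated 57-subject cohorts (fitted
with 2 chains × 600 iterations, ample for two posterior moments) for
cluster-number recovery, 10,000 null simulations for the circular
test's calibration, and 50 label permutations for the classifier's
null.  Scale parameters are floored at 1e-6 (log-degrees — effectively
zero noise) so degenerate, noise-free inputs stay proper; sums of
squares are floored at 1e-12; slice sampling uses unit step width with
stepping-out capped at 50 steps.  Ties in silhouette selection go to
the smaller k; ties in cluster relabeling follow descending cluster
mean improvement.

## Known limitations

* The sigma_eta/sigma_y split is prior-identified only; report the
  total scale, not the split.
* Near-chance subjects have wide, right-skewed state posteriors under
  the bounded observation model; point summaries (posterior means) of
  such subjects sit above the data mean by construction.
* PSIS-LOO magnitudes under the default local conditioning are
  optimistic and flagged; use the state conditioning when magnitude
  matters.
* The subgroup structure is a property of a given sample, not of the
  population; the silhouette curve is shallow between k = 4 and 7, and
  single cohorts can select a neighboring k.
* The classifier is a two-feature logistic regression evaluated on
  small cohorts; fold AUCs are high-variance.
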