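import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from navlearn.cohort import (
    ArchetypeSpec,
    ConstraintError,
    DEFAULT_ARCHETYPES,
    DEFAULT_MIX,
    behavioral_schedule,
    build_schedule,
    fmri_schedule,
    simulate_cohort,
    simulate_subject,
)
from navlearn.io import ConfigError


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "spec,n_retrieval,per_block,n_control",
    [(behavioral_schedule(), 96, 12, 0), (fmri_schedule(), 64, 8, 32)],
)
def test_schedule_emits_expected_counts(spec, n_retrieval, per_block, n_control):
    plan = build_schedule(spec, seed=0)
    retrieval = plan[plan["trial_kind"] == "retrieval"]
    control = plan[plan["trial_kind"] == "control"]
    assert len(retrieval) == n_retrieval
    assert len(control) == n_control
    assert (retrieval.groupby("block").size() == per_block).all()


@pytest.mark.parametrize("spec", [behavioral_schedule(), fmri_schedule()],
                         ids=["behavioral", "fmri"])
@pytest.mark.parametrize("seed", [0, 1, 17])
def test_schedule_cell_balance_exhaustive(spec, seed):
    """Every intersection x direction x target cell appears exactly
    `repetitions` times among retrieval trials (conservation of the
    factorial design)."""
    plan = build_schedule(spec, seed=seed)
    retrieval = plan[plan["trial_kind"] == "retrieval"]
    counts = retrieval.groupby(["intersection", "direction", "target"]).size()
    assert len(counts) == 32
    assert (counts == spec.repetitions).all()


@pytest.mark.parametrize("seed", [0, 5, 11])
def test_direction_split_constraint_exhaustive(seed):
    """With the midpoint direction change, each intersection/target pair is
    approached from exactly two directions in each experiment half."""
    spec = behavioral_schedule()
    plan = build_schedule(spec, seed=seed)
    retrieval = plan[plan["trial_kind"] == "retrieval"]
    half = np.where(retrieval["block"] <= spec.blocks // 2, 1, 2)
    for (i, t), grp in retrieval.groupby(["intersection", "target"]):
        h = half[grp.index]
        dirs1 = set(grp.loc[h == 1, "direction"])
        dirs2 = set(grp.loc[h == 2, "direction"])
        assert len(dirs1) == 2 and len(dirs2) == 2
        assert dirs1.isdisjoint(dirs2)


def test_schedule_reproducible_from_seed():
    spec = behavioral_schedule()
    assert build_schedule(spec, seed=4).equals(build_schedule(spec, seed=4))
    assert not build_schedule(spec, seed=4).equals(build_schedule(spec, seed=5))


def test_infeasible_schedule_rejected_before_emission():
    with pytest.raises(ConstraintError):
        build_schedule(behavioral_schedule().__class__(repetitions=0), seed=0)
    with pytest.raises(ConstraintError):
        build_schedule(behavioral_schedule().__class__(
            repetitions=2, retrieval_per_block=12), seed=0)


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------


def test_subject_simulation_deterministic(behavioral_spec):
    plan = build_schedule(behavioral_spec, seed=2)
    a, ta = simulate_subject(DEFAULT_ARCHETYPES["weak"], plan, "old", seed=9,
                             spec=behavioral_spec)
    b, tb = simulate_subject(DEFAULT_ARCHETYPES["weak"], plan, "old", seed=9,
                             spec=behavioral_spec)
    assert a.equals(b)
    assert np.array_equal(ta, tb)


def test_simulated_errors_within_physical_bounds(behavioral_spec):
    plan = build_schedule(behavioral_spec, seed=2)
    for name, arch in DEFAULT_ARCHETYPES.items():
        trials, truth = simulate_subject(arch, plan, "old", seed=5,
                                         spec=behavioral_spec)
        obs = trials.loc[~trials["missing"], "abs_error"]
        assert ((obs > 0) & (obs <= 180)).all(), name
        assert ((truth >= 1) & (truth <= 180)).all(), name


def _truncated_lognormal_mean(m: float, sd: float, upper: float = 180.0) -> float:
    """Closed-form mean of a lognormal(m, sd) conditioned on y <= upper."""
    a = (math.log(upper) - m) / sd
    return math.exp(m + sd**2 / 2) * norm.cdf(a - sd) / norm.cdf(a)


def test_trial_noise_matches_truncated_lognormal_oracle(behavioral_spec):
    """Flat archetype, many subjects: per-block mean error agrees with the
    closed-form truncated-lognormal mean implied by the latent state."""
    arch = ArchetypeSpec("flat", initial_state=90.0, drift=0.0,
                         state_jitter=1e-6, trial_noise_sd=0.5,
                         missing_prob=0.0)
    plan = build_schedule(behavioral_spec, seed=0)
    errors = []
    for s in range(120):
        trials, _ = simulate_subject(arch, plan, "young", seed=10_000 + s,
                                     spec=behavioral_spec)
        errors.append(trials["abs_error"].to_numpy())
    errors = np.concatenate(errors)  # ~11,500 draws
    expected = _truncated_lognormal_mean(math.log(90.0), 0.5)
    se = errors.std() / math.sqrt(len(errors))
    assert abs(errors.mean() - expected) < 4 * se


def test_missingness_rate_matches_binomial_oracle(behavioral_spec):
    arch = ArchetypeSpec("m", initial_state=60.0, drift=0.0, state_jitter=1e-6,
                         trial_noise_sd=0.3, missing_prob=0.05)
    plan = build_schedule(behavioral_spec, seed=0)
    n_missing = 0
    n_total = 0
    for s in range(110):
        trials, _ = simulate_subject(arch, plan, "young", seed=20_000 + s,
                                     spec=behavioral_spec)
        n_missing += int(trials["missing"].sum())
        n_total += len(trials)
    p_hat = n_missing / n_total
    se = math.sqrt(0.05 * 0.95 / n_total)
    assert abs(p_hat - 0.05) < 3 * se


def test_latent_trajectory_decreasing_in_expectation(behavioral_spec):
    plan = build_schedule(behavioral_spec, seed=0)
    truths = []
    for s in range(60):
        _, truth = simulate_subject(DEFAULT_ARCHETYPES["good"], plan, "young",
                                    seed=30_000 + s, spec=behavioral_spec)
        truths.append(truth)
    mean_traj = np.mean(truths, axis=0)
    assert (np.diff(mean_traj) < 0).all()


def test_block5_rt_bump_only_for_old_with_direction_split(behavioral_spec):
    arch = ArchetypeSpec("rt", initial_state=60.0, drift=0.0, state_jitter=1e-6,
                         trial_noise_sd=0.3, missing_prob=0.0,
                         rt_base=6.0, rt_slope=0.0, rt_block5_bump=1.5)
    plan = build_schedule(behavioral_spec, seed=0)

    def mean_gap(age):
        gaps = []
        for s in range(150):
            trials, _ = simulate_subject(arch, plan, age, seed=40_000 + s,
                                         spec=behavioral_spec)
            rt = trials.groupby("block")["response_time"].mean()
            gaps.append(rt[5] - rt[4])
        return float(np.mean(gaps))

    assert mean_gap("old") == pytest.approx(1.5, abs=0.2)
    assert mean_gap("young") == pytest.approx(0.0, abs=0.2)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def test_cohort_emits_requested_subjects():
    trials, truth = simulate_cohort(n_young=25, n_old=32, seed=0)
    assert trials["subject_id"].nunique() == 57
    assert truth["subject_id"].nunique() == 57
    labels = truth.drop_duplicates("subject_id")
    assert (labels["age_group"] == "young").sum() == 25
    assert (labels["age_group"] == "old").sum() == 32


def test_single_archetype_mix_yields_uniform_labels():
    mix = {"young": {"non": 1.0}, "old": {"non": 1.0}}
    _, truth = simulate_cohort(mix=mix, n_young=3, n_old=3, seed=1)
    assert set(truth["archetype"]) == {"non"}


def test_invalid_mix_proportions_rejected():
    mix = {"young": {"top": 0.5, "good": 0.2}, "old": {"non": 1.0}}
    with pytest.raises(ConfigError, match="sum"):
        simulate_cohort(mix=mix, n_young=2, n_old=2, seed=0)


def test_archetype_counts_match_multinomial_oracle():
    _, truth = simulate_cohort(n_young=100, n_old=100, seed=3)
    labels = truth.drop_duplicates("subject_id")
    for group, n in (("young", 100), ("old", 100)):
        counts = labels[labels["age_group"] == group]["archetype"].value_counts()
        for name, p in DEFAULT_MIX[group].items():
            se = math.sqrt(n * p * (1 - p))
            assert abs(counts.get(name, 0) - n * p) <= max(3 * se, 1), (group, name)


def test_cohort_reproducible_and_order_independent():
    t1, _ = simulate_cohort(n_young=3, n_old=3, seed=5)
    t2, _ = simulate_cohort(n_young=3, n_old=3, seed=5)
    assert t1.equals(t2)
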