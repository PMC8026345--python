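"""Synthetic trial schedules and cohorts with known ground truth.

Two schedule presets mirror the two experiments: a behavioral session of
8 learning blocks x 12 pointing trials (96 retrieval trials = 4
intersections x 4 approach directions x 2 target landmarks x 3
repetitions, with the approach directions split between experiment
halves) and an fMRI session of 8 blocks x 8 retrieval + 4 control trials
(64 retrieval = same factorial with 2 repetitions, 32 control trials, no
direction split).

Subjects are simulated from five learner archetypes (top, good,
intermediate, weak, non-learner).  Each archetype plants a latent
per-block error level that decays linearly with random-walk jitter;
observed absolute errors are drawn lognormally around that level
(truncated at the physical 180 deg bound by resampling), timeouts occur
with a per-archetype probability, and response times decline over blocks
with an extra block-5 bump for older subjects when the approach
directions change at the session midpoint.  The archetype constants are
fixed package defaults chosen so that the five archetypes are separable
in (difference-mean, difference-SD) feature space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from navlearn.io import (
    AGE_GROUPS,
    DIRECTIONS,
    INTERSECTIONS,
    TARGETS,
    ConfigError,
    TrialRecord,
    records_to_frame,
)

__all__ = [
    "ScheduleSpec",
    "ArchetypeSpec",
    "ConstraintError",
    "behavioral_schedule",
    "fmri_schedule",
    "build_schedule",
    "simulate_subject",
    "simulate_cohort",
    "DEFAULT_ARCHETYPES",
    "DEFAULT_MIX",
]

RT_FLOOR = 0.3  # seconds; fastest physically plausible confirmed response
RT_NOISE_SD = 0.8  # seconds


class ConstraintError(ValueError):
    """The schedule specification is infeasible."""


@dataclass(frozen=True)
class ScheduleSpec:
    """Factorial design of one session."""

    blocks: int = 8
    retrieval_per_block: int = 12
    control_per_block: int = 0
    repetitions: int = 3
    timeout: float = 12.0
    direction_split: bool = True
    n_intersections: int = 4
    n_directions: int = 4
    n_targets: int = 2

    def validate(self) -> None:
        n_cells = self.n_intersections * self.n_directions * self.n_targets
        total = n_cells * self.repetitions
        if self.repetitions < 1:
            raise ConstraintError("repetitions must be >= 1 (no trials to schedule)")
        if total != self.blocks * self.retrieval_per_block:
            raise ConstraintError(
                f"{n_cells} design cells x {self.repetitions} repetitions = {total} "
                f"trials do not fill {self.blocks} blocks x "
                f"{self.retrieval_per_block} retrieval trials"
            )
        if self.direction_split:
            if self.blocks % 2 or self.n_directions % 2:
                raise ConstraintError(
                    "direction split needs an even number of blocks and directions"
                )
        if self.control_per_block:
            n_control = self.blocks * self.control_per_block
            if n_control % (self.n_intersections * self.n_directions):
                raise ConstraintError(
                    "control trials do not balance over intersections x directions"
                )

    @property
    def n_retrieval(self) -> int:
        return self.blocks * self.retrieval_per_block

    @property
    def n_control(self) -> int:
        return self.blocks * self.control_per_block


def behavioral_schedule() -> ScheduleSpec:
    """The behavioral session: 96 retrieval trials, direction split at midpoint."""
    return ScheduleSpec(
        blocks=8,
        retrieval_per_block=12,
        control_per_block=0,
        repetitions=3,
        direction_split=True,
    )


def fmri_schedule() -> ScheduleSpec:
    """The fMRI session: 64 retrieval + 32 control trials, no direction split."""
    return ScheduleSpec(
        blocks=8,
        retrieval_per_block=8,
        control_per_block=4,
        repetitions=2,
        direction_split=False,
    )


def schedule_preset(name: str) -> ScheduleSpec:
    try:
        return {"behavioral": behavioral_schedule, "fmri": fmri_schedule}[name]()
    except KeyError:
        raise ConfigError(f"unknown schedule preset {name!r}") from None


def build_schedule(spec: ScheduleSpec, seed: int) -> pd.DataFrame:
    """Emit a pseudo-randomized, exactly balanced trial plan.

    Every intersection x direction x target cell appears exactly
    ``spec.repetitions`` times among retrieval trials.  With
    ``direction_split`` each intersection/target pair is approached from
    two of the four directions in the first half of the session and from
    the other two in the second half.  Any constraint-satisfying shuffle
    is acceptable; this one is reproducible from ``seed``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    intersections = INTERSECTIONS[: spec.n_intersections]
    directions = DIRECTIONS[: spec.n_directions]
    targets = TARGETS[: spec.n_targets]

    if spec.direction_split:
        halves: list[list[tuple[str, str, str]]] = [[], []]
        for i, t in itertools.product(intersections, targets):
            first = rng.choice(spec.n_directions, size=spec.n_directions // 2,
                               replace=False)
            for d_idx in range(spec.n_directions):
                half = 0 if d_idx in first else 1
                halves[half].extend(
                    [(i, directions[d_idx], t)] * spec.repetitions
                )
        plans = []
        for half, cells in enumerate(halves):
            order = rng.permutation(len(cells))
            plans.append([cells[j] for j in order])
        retrieval = plans[0] + plans[1]
    else:
        cells = [
            (i, d, t)
            for i, d, t in itertools.product(intersections, directions, targets)
        ] * spec.repetitions
        order = rng.permutation(len(cells))
        retrieval = [cells[j] for j in order]

    rows = []
    for idx, (i, d, t) in enumerate(retrieval):
        rows.append(
            {
                "block": idx // spec.retrieval_per_block + 1,
                "trial_in_block": idx % spec.retrieval_per_block + 1,
                "intersection": i,
                "direction": d,
                "target": t,
                "trial_kind": "retrieval",
            }
        )

    if spec.control_per_block:
        n_cells = spec.n_intersections * spec.n_directions * spec.n_targets
        reps = max(spec.n_control // n_cells, 1)
        control_cells = ([
            (i, d, t)
            for i, d, t in itertools.product(intersections, directions, targets)
        ] * reps)[: spec.n_control]
        order = rng.permutation(len(control_cells))
        for idx, j in enumerate(order):
            i, d, t = control_cells[j]
            rows.append(
                {
                    "block": idx // spec.control_per_block + 1,
                    "trial_in_block": spec.retrieval_per_block
                    + idx % spec.control_per_block
                    + 1,
                    "intersection": i,
                    "direction": d,
                    "target": t,
                    "trial_kind": "control",
                }
            )

    plan = pd.DataFrame(rows).sort_values(
        ["block", "trial_in_block"], kind="stable"
    )
    return plan.reset_index(drop=True)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters of one learner archetype.

    ``initial_state`` is the latent absolute-error level (degrees) in
    block 1; ``drift`` the expected per-block decrease; ``state_jitter``
    the SD of the latent random-walk innovations; ``trial_noise_sd`` the
    log-scale SD of trial errors around the latent level;
    ``rt_block5_bump`` is added to response times in block 5 only for
    older subjects under a direction-split schedule (viewpoint-change
    perturbation).
    """

    name: str
    initial_state: float
    drift: float
    state_jitter: float
    trial_noise_sd: float
    missing_prob: float
    rt_base: float = 6.0
    rt_slope: float = 0.3
    rt_block5_bump: float = 1.5

    def validate(self) -> None:
        if not 0 < self.initial_state <= 180:
            raise ConfigError(f"initial_state {self.initial_state} outside (0, 180]")
        if self.state_jitter <= 0 or self.trial_noise_sd <= 0:
            raise ConfigError("state_jitter and trial_noise_sd must be > 0")
        if not 0 <= self.missing_prob <= 0.2:
            raise ConfigError(f"missing_prob {self.missing_prob} outside [0, 0.2]")


#: Fixed archetype constants (package defaults, not estimates): chosen so
#: the archetypes are separable in (difference-mean, difference-SD) space.
DEFAULT_ARCHETYPES: dict[str, ArchetypeSpec] = {
    "top": ArchetypeSpec(
        "top", initial_state=25.0, drift=1.5, state_jitter=1.0,
        trial_noise_sd=0.20, missing_prob=0.01, rt_base=4.5, rt_slope=0.25,
    ),
    "good": ArchetypeSpec(
        "good", initial_state=60.0, drift=7.0, state_jitter=1.0,
        trial_noise_sd=0.25, missing_prob=0.01, rt_base=5.0, rt_slope=0.35,
    ),
    "intermediate": ArchetypeSpec(
        "intermediate", initial_state=75.0, drift=10.0, state_jitter=1.2,
        trial_noise_sd=0.32, missing_prob=0.03, rt_base=6.5, rt_slope=0.30,
    ),
    "weak": ArchetypeSpec(
        "weak", initial_state=80.0, drift=4.5, state_jitter=1.0,
        trial_noise_sd=0.33, missing_prob=0.05, rt_base=7.0, rt_slope=0.25,
    ),
    "non": ArchetypeSpec(
        "non", initial_state=78.0, drift=0.5, state_jitter=1.0,
        trial_noise_sd=0.25, missing_prob=0.08, rt_base=7.0, rt_slope=0.15,
    ),
}

#: Default archetype mixing proportions per age group, mirroring the
#: subgroup composition observed in the fMRI cohort (57 subjects: 9 top
#: of which 7 young / 2 old, 14 good all young, 9 intermediate 3/6,
#: 12 weak all old, 13 non 1/12).
DEFAULT_MIX: dict[str, dict[str, float]] = {
    "young": {"top": 7 / 25, "good": 14 / 25, "intermediate": 3 / 25,
              "weak": 0.0, "non": 1 / 25},
    "old": {"top": 2 / 32, "good": 0.0, "intermediate": 6 / 32,
            "weak": 12 / 32, "non": 12 / 32},
}


def _truncated_lognormal(rng: np.random.Generator, log_mean: float,
                         sdlog: float, size: int, upper: float = 180.0) -> np.ndarray:
    """Lognormal draws resampled until <= upper (physical pointing bound)."""
    out = rng.lognormal(log_mean, sdlog, size=size)
    bad = out > upper
    while bad.any():
        out[bad] = rng.lognormal(log_mean, sdlog, size=int(bad.sum()))
        bad = out > upper
    return out


def simulate_latent_trajectory(
    archetype: ArchetypeSpec, blocks: int, rng: np.random.Generator
) -> np.ndarray:
    """Planted per-block latent error level s_b, degrees, clamped to [1, 180]."""
    jitter = np.concatenate([[0.0], rng.normal(0.0, archetype.state_jitter, blocks - 1)])
    walk = np.cumsum(jitter)
    s = archetype.initial_state - archetype.drift * np.arange(blocks) + walk
    return np.clip(s, 1.0, 180.0)


def simulate_subject(
    archetype: ArchetypeSpec,
    schedule: pd.DataFrame,
    age_group: str,
    seed: int | np.random.Generator,
    spec: ScheduleSpec | None = None,
    subject_id: str = "S01",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one subject's trials; returns (trials, latent trajectory).

    The latent trajectory is the planted ground truth s_b (degrees per
    block) that parameter-recovery tests compare against exp(mu_b).
    """
    archetype.validate()
    if age_group not in AGE_GROUPS:
        raise ConfigError(f"unknown age_group {age_group!r}")
    spec = spec if spec is not None else _infer_spec(schedule)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    blocks = int(schedule["block"].max())
    truth = simulate_latent_trajectory(archetype, blocks, rng)
    bump_block = blocks // 2 + 1 if (spec.direction_split and age_group == "old") else -1

    records: list[TrialRecord] = []
    for row in schedule.itertuples(index=False):
        b = int(row.block)
        if row.trial_kind == "control":
            # color-judgment control task: ceiling accuracy placeholder
            abs_err = float(_truncated_lognormal(rng, math.log(6.0), 0.4, 1)[0])
            rt = float(np.clip(3.0 + rng.normal(0, 0.5), RT_FLOOR, spec.timeout))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            records.append(
                TrialRecord(
                    subject_id, age_group, b, int(row.trial_in_block),
                    row.intersection, row.direction, row.target, "control",
                    abs_error=abs_err, signed_error=sign * abs_err,
                    response_time=rt, missing=False,
                )
            )
            continue
        if rng.random() < archetype.missing_prob:
            records.append(
                TrialRecord(
                    subject_id, age_group, b, int(row.trial_in_block),
                    row.intersection, row.direction, row.target, "retrieval",
                    missing=True,
                )
            )
            continue
        abs_err = float(
            _truncated_lognormal(rng, math.log(truth[b - 1]), archetype.trial_noise_sd, 1)[0]
        )
        sign = 1.0 if rng.random() < 0.5 else -1.0
        signed = 180.0 if abs_err == 180.0 else sign * abs_err
        rt = archetype.rt_base - archetype.rt_slope * (b - 1)
        if b == bump_block:
            rt += archetype.rt_block5_bump
        rt = float(np.clip(rt + rng.normal(0, RT_NOISE_SD), RT_FLOOR, spec.timeout))
        records.append(
            TrialRecord(
                subject_id, age_group, b, int(row.trial_in_block),
                row.intersection, row.direction, row.target, "retrieval",
                abs_error=abs_err, signed_error=signed,
                response_time=rt, missing=False,
            )
        )
    return records_to_frame(records), truth


def _infer_spec(schedule: pd.DataFrame) -> ScheduleSpec:
    retrieval = schedule[schedule["trial_kind"] == "retrieval"]
    control = schedule[schedule["trial_kind"] == "control"]
    blocks = int(schedule["block"].max())
    reps = len(retrieval) // (4 * 4 * 2)
    return ScheduleSpec(
        blocks=blocks,
        retrieval_per_block=len(retrieval) // blocks,
        control_per_block=len(control) // blocks,
        repetitions=max(reps, 1),
        direction_split=False,
    )


def simulate_cohort(
    mix: dict[str, dict[str, float]] | None = None,
    n_young: int = 25,
    n_old: int = 32,
    seed: int = 0,
    spec: ScheduleSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (trials, truth).

    ``truth`` is a long DataFrame with one row per subject-block carrying
    the archetype label and planted latent state.  Subjects are simulated
    from independent counter-based substreams of ``seed``, so results do
    not depend on simulation order.
    """
    mix = mix if mix is not None else DEFAULT_MIX
    spec = spec if spec is not None else behavioral_schedule()
    for group, probs in mix.items():
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigError(
                f"archetype proportions for {group!r} sum to {total}, not 1"
            )

    trial_frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    counts = {"young": n_young, "old": n_old}
    subject_index = 0
    for group in ("young", "old"):
        names = sorted(mix[group])
        probs = np.array([mix[group][n] for n in names])
        assign_rng = np.random.default_rng([seed, 0 if group == "young" else 1])
        labels = assign_rng.choice(names, size=counts[group], p=probs)
        for j in range(counts[group]):
            subject_index += 1
            sid = f"{'Y' if group == 'young' else 'O'}{j + 1:02d}"
            sub_rng = np.random.default_rng([seed, 2, subject_index])
            plan = build_schedule(spec, seed=int(sub_rng.integers(2**31)))
            trials, truth = simulate_subject(
                DEFAULT_ARCHETYPES[labels[j]], plan, group, sub_rng,
                spec=spec, subject_id=sid,
            )
            trial_frames.append(trials)
            for b, s in enumerate(truth, start=1):
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "age_group": group,
                        "archetype": labels[j],
                        "block": b,
                        "latent_state": float(s),
                    }
                )
    trials = pd.concat(trial_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth
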