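"""Derived learning quantities: curves, amount of learning, difference features.

All summaries are on the degrees scale exp(mu), matching how learning
curves are plotted; the amount of learning L_b is the block-to-block
decrease in the estimated state with block 1 referenced to the chance
level (90 deg under uniform pointing), so improvement that already
happened during familiarization is credited to block 1.  Mean-centered,
unit-norm L vectors serve as fMRI contrast weights over per-block
regressors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from navlearn.statespace import StateSpacePosterior

__all__ = ["LearningCurve", "AmountOfLearning", "DifferenceFeature",
           "learning_curve", "amount_of_learning", "difference_feature"]

_MIN_STABLE_DRAWS = 100


@dataclass
class LearningCurve:
    """Per-block posterior mean and SD of the learning state, degrees."""

    subject_id: str
    mean: np.ndarray
    sd: np.ndarray

    @property
    def n_blocks(self) -> int:
        return len(self.mean)


@dataclass
class AmountOfLearning:
    """Per-block learning increments L_b and derived contrast weights.

    Telescoping identity: sum(L) == chance_level - mean[last block].
    ``weights`` are L mean-centered and scaled to unit Euclidean norm;
    for a perfectly flat curve at chance the weights are all zero and
    ``degenerate`` is set instead of raising.
    """

    subject_id: str
    L: np.ndarray
    mean_amount: float
    weights: np.ndarray
    chance_level: float
    degenerate: bool = False


@dataclass
class DifferenceFeature:
    """Normal fit to the posterior first-minus-last state difference.

    ``diff_mean`` > 0 means improvement (the block-1 state exceeds the
    final state); ``diff_sd`` captures the subject's estimation
    uncertainty.  These two numbers are the clustering feature space.
    """

    subject_id: str
    diff_mean: float
    diff_sd: float


def learning_curve(posterior: StateSpacePosterior) -> LearningCurve:
    """Posterior mean/SD of exp(mu_b) per block over all retained draws.

    For the trial-wise model the per-trial states are first averaged
    within blocks (per draw) so both model variants yield curves on the
    same per-block grid.
    """
    if posterior.total_draws == 0:
        raise ValueError("empty posterior")
    draws = posterior.state_draws_deg()  # (draws, states)
    if posterior.model != "block":
        blocks = np.asarray(posterior.meta["block_of_trial"], int)
        n_blocks = int(posterior.meta["n_blocks"])
        cols = [draws[:, blocks == b].mean(axis=1) for b in range(1, n_blocks + 1)]
        draws = np.column_stack(cols)
    return LearningCurve(
        subject_id=str(posterior.meta.get("subject_id", "")),
        mean=draws.mean(axis=0),
        sd=draws.std(axis=0),
    )


def amount_of_learning(curve: LearningCurve,
                       chance_level: float = 90.0) -> AmountOfLearning:
    """Per-block learning increments from a fitted curve.

    L_1 = chance_level - mean_1 (learning already achieved before the
    first retrieval phase); L_b = mean_{b-1} - mean_b for b >= 2.
    """
    if curve.n_blocks < 2:
        raise ValueError("need >= 2 blocks to compute learning increments")
    L = np.empty(curve.n_blocks)
    L[0] = chance_level - curve.mean[0]
    L[1:] = -np.diff(curve.mean)
    centered = L - L.mean()
    norm = float(np.linalg.norm(centered))
    if norm < 1e-12:
        weights = np.zeros_like(L)
        degenerate = True
    else:
        weights = centered / norm
        degenerate = False
    return AmountOfLearning(
        subject_id=curve.subject_id, L=L, mean_amount=float(L.mean()),
        weights=weights, chance_level=chance_level, degenerate=degenerate,
    )


def difference_feature(posterior: StateSpacePosterior) -> DifferenceFeature:
    """Gaussian fit to the posterior distribution of exp(mu_1) - exp(mu_B).

    The maximum-likelihood normal fit is exactly the sample mean and
    (population) SD of the per-draw differences.
    """
    draws = posterior.state_draws_deg()
    if posterior.model != "block":
        blocks = np.asarray(posterior.meta["block_of_trial"], int)
        n_blocks = int(posterior.meta["n_blocks"])
        first = draws[:, blocks == 1].mean(axis=1)
        last = draws[:, blocks == n_blocks].mean(axis=1)
    else:
        first = draws[:, 0]
        last = draws[:, -1]
    if len(first) < _MIN_STABLE_DRAWS:
        warnings.warn(
            f"only {len(first)} draws: difference-SD estimate is unstable",
            stacklevel=2,
        )
    d = first - last
    return DifferenceFeature(
        subject_id=str(posterior.meta.get("subject_id", "")),
        diff_mean=float(d.mean()),
        diff_sd=float(d.std()),
    )
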