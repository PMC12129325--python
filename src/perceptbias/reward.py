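"""Reward allocation strategies and the boundary-tracking state.

The proposed method rewards a choice relative to a per-condition reward
boundary placed at the current posterior-mean estimate of that
condition's perceptual bias (neutral stays at 0): a leftward choice is
rewarded iff the stimulus lies left of the boundary, rightward iff
right of it.  The boundary is clamped to move at most ``max_step`` deg
per trial (1 deg, i.e. 1% of the stimulus range, by default), and before
the first posterior is available (t < 33) it sits at the prior mean.

Conventional comparison strategies: veridical (boundary 0 everywhere),
oracle (boundary at the ground-truth perceptual bias, simulation only),
and the three ambiguous-trial variants (random / always / never reward
when the stimulus falls between the veridical boundary and the
condition's true perceptual bias, veridical otherwise).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .psychometric import BiasSet, ConditionLabel, TrialRecord


class StrategyKind(str, enum.Enum):
    VERIDICAL = "veridical"
    RANDOM_AMBIGUOUS = "random_ambiguous"
    ALWAYS_AMBIGUOUS = "always_ambiguous"
    NEVER_AMBIGUOUS = "never_ambiguous"
    ORACLE = "oracle"
    ESTIMATED = "estimated"


@dataclass(frozen=True)
class RewardStrategy:
    kind: StrategyKind
    #: reward probability on ambiguous trials (random_ambiguous only);
    #: prior studies used 50-100%, 0.5 is the default here
    random_prob: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.random_prob <= 1.0):
            raise ValueError("random_prob must lie in [0, 1]")

    @property
    def needs_truth(self) -> bool:
        return self.kind in (
            StrategyKind.ORACLE,
            StrategyKind.RANDOM_AMBIGUOUS,
            StrategyKind.ALWAYS_AMBIGUOUS,
            StrategyKind.NEVER_AMBIGUOUS,
        )


@dataclass(frozen=True)
class RewardState:
    """Current per-condition reward boundaries for the estimated strategy."""

    boundary_L: float = 0.0
    boundary_R: float = 0.0
    last_update_trial: int = 0
    max_step: float = 1.0

    def boundary(self, condition: ConditionLabel) -> float:
        if condition is ConditionLabel.L:
            return self.boundary_L
        if condition is ConditionLabel.R:
            return self.boundary_R
        return 0.0  # neutral condition has no perceptual bias to track


def decide_reward(choice: int, omega: float, boundary: float) -> bool:
    """Reward rule relative to a boundary (deg): left choices are correct
    strictly below it, right choices strictly above it.  A stimulus exactly
    on the boundary is never rewarded (neither allocation branch applies);
    for continuous, posterior-driven boundaries this tie is measure-zero,
    but for the veridical boundary it recurs at the grid's zero stimulus,
    and rewarding it would put the unbiased boundary at a reward-rate
    disadvantage relative to off-stimulus boundaries."""
    if not (np.isfinite(omega) and np.isfinite(boundary)):
        raise ValueError("omega and boundary must be finite")
    if choice == -1:
        return omega < boundary
    if choice == 1:
        return omega > boundary
    raise ValueError("choice must be +/-1")


def is_ambiguous(omega: float, condition: ConditionLabel, truth: BiasSet) -> bool:
    """A biased-condition trial whose stimulus lies in the closed interval
    between the veridical boundary (0) and the condition's true perceptual
    bias; in that band the 'correct' answer is undefined."""
    if condition is ConditionLabel.N:
        return False
    p = truth.perceptual(condition)
    lo, hi = min(0.0, p), max(0.0, p)
    return lo <= omega <= hi


def strategy_reward(
    strategy: RewardStrategy,
    trial: TrialRecord,
    truth: BiasSet | None = None,
    state: RewardState | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[bool, float]:
    """Apply a reward strategy to one trial; returns (reward, boundary used).

    The ambiguous variants fall back to the veridical rule outside the
    ambiguous band; their 'boundary used' is the veridical 0 (the special
    handling applies only inside the band, where no boundary is defined).
    """
    kind = strategy.kind
    if strategy.needs_truth and truth is None:
        raise ValueError(f"strategy {kind.value!r} requires ground-truth biases")

    if kind is StrategyKind.VERIDICAL:
        return decide_reward(trial.choice, trial.omega, 0.0), 0.0
    if kind is StrategyKind.ORACLE:
        b = truth.perceptual(trial.condition)
        return decide_reward(trial.choice, trial.omega, b), b
    if kind is StrategyKind.ESTIMATED:
        if state is None:
            raise ValueError("estimated strategy requires a RewardState")
        b = state.boundary(trial.condition)
        return decide_reward(trial.choice, trial.omega, b), b

    # ambiguous-band variants
    if is_ambiguous(trial.omega, trial.condition, truth):
        if kind is StrategyKind.ALWAYS_AMBIGUOUS:
            return True, 0.0
        if kind is StrategyKind.NEVER_AMBIGUOUS:
            return False, 0.0
        if rng is None:
            raise ValueError("random_ambiguous requires an rng")
        return bool(rng.random() < strategy.random_prob), 0.0
    return decide_reward(trial.choice, trial.omega, 0.0), 0.0


def clamp_boundary(previous: float, proposal: float, max_step: float) -> float:
    """Move a boundary toward a proposal by at most ``max_step`` degrees."""
    return previous + float(np.clip(proposal - previous, -max_step, max_step))


def update_boundary(
    state: RewardState,
    proposal_L: float,
    proposal_R: float,
    trial_index: int,
) -> RewardState:
    """Advance the reward boundaries toward posterior-mean proposals.

    Only the perceptual-bias means enter the boundary — the decision-bias
    estimate is never added (the boundary lives in stimulus coordinates
    around the task reference).
    """
    return replace(
        state,
        boundary_L=clamp_boundary(state.boundary_L, proposal_L, state.max_step),
        boundary_R=clamp_boundary(state.boundary_R, proposal_R, state.max_step),
        last_update_trial=trial_index,
    )


def initial_state(priors, max_step: float = 1.0) -> RewardState:
    """Boundaries before the first posterior (t < 33): the prior means of
    the perceptual biases."""
    return RewardState(
        boundary_L=priors.P_L.mean,
        boundary_R=priors.P_R.mean,
        last_update_trial=0,
        max_step=max_step,
    )
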