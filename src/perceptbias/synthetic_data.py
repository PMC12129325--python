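"""Ground-truth 2AFC session generator.

Sessions emulate the motion-discrimination validation setup: 11 target
directions from -40 to +40 deg in 8-deg steps, three interleaved
contextual conditions (leftward / neutral / rightward self-motion), and
block randomization — every one of the 33 unique (direction, condition)
stimuli appears exactly once per block, in a fresh seeded permutation.
Thirty blocks give the standard 990-trial session.

Choices are drawn from the observer model (cumulative Gaussian with
empirical bias ``B_k = P_k + D``); simulations use zero lapse rates.
Biases can be stationary, drift sinusoidally (decision bias), or decay
piecewise-linearly across sessions (perceptual bias).  An optional
win-stay/lose-shift channel replaces the stimulus-driven choice with a
history-driven one on a random fraction of trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .psychometric import (
    CONDITION_ORDER,
    BiasSet,
    ConditionLabel,
    PsychometricParams,
    TrialRecord,
    choice_prob,
)

DEFAULT_GRID: tuple[float, ...] = tuple(float(v) for v in range(-40, 41, 8))


@dataclass(frozen=True)
class SessionDesign:
    """Block-randomized stimulus schedule for one session."""

    grid: tuple[float, ...] = DEFAULT_GRID
    n_blocks: int = 30
    seed: int = 0
    #: per-condition grid offsets (deg); used by the symmetric-grid RL variant
    #: where each condition's grid is translated by its true perceptual bias
    grid_offsets: dict[ConditionLabel, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.grid) == 0:
            raise ValueError("stimulus grid must be nonempty")
        if any(b >= a for a, b in zip(self.grid[1:], self.grid)):
            raise ValueError("stimulus grid must be strictly increasing")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * len(self.grid) * len(CONDITION_ORDER)

    def stimulus_order(self) -> list[tuple[ConditionLabel, float]]:
        """The session's (condition, omega) sequence under block randomization."""
        rng = np.random.default_rng(self.seed)
        pairs = [
            (cond, om + self.grid_offsets.get(cond, 0.0))
            for cond in CONDITION_ORDER
            for om in self.grid
        ]
        order: list[tuple[ConditionLabel, float]] = []
        for _ in range(self.n_blocks):
            perm = rng.permutation(len(pairs))
            order.extend(pairs[i] for i in perm)
        return order


def make_design(
    grid: Sequence[float] = DEFAULT_GRID,
    n_blocks: int = 30,
    seed: int = 0,
    grid_offsets: dict[ConditionLabel, float] | None = None,
) -> SessionDesign:
    """Build a :class:`SessionDesign` (990 trials at the defaults)."""
    return SessionDesign(
        grid=tuple(float(g) for g in grid),
        n_blocks=n_blocks,
        seed=seed,
        grid_offsets=dict(grid_offsets or {}),
    )


# ---------------------------------------------------------------------------
# time-varying biases
# ---------------------------------------------------------------------------


def decision_bias_at(n) -> float | np.ndarray:
    """Slowly drifting decision bias used in the robustness scenario:
    ``D_n = 10 sin(pi n / 2000)`` for trial index ``n``."""
    return 10.0 * np.sin(np.pi * np.asarray(n, dtype=float) / 2000.0)[()]


@dataclass(frozen=True)
class GradualChangeSpec:
    """Piecewise-linear decay of a perceptual bias from ``P0`` to ``P0/s``.

    The bias holds at ``P0`` through trial ``t_b1``, declines linearly,
    and plateaus at ``P0/s`` from trial ``t_b2`` on.  The multi-session
    default (steepness 3, change spanning sessions 11-41 of 990-trial
    sessions) uses ``t_b1 = 10*990`` and ``t_b2 = 41*990``.
    """

    P0: float
    s: float = 3.0
    t_b1: int = 10 * 990
    t_b2: int = 41 * 990

    def __post_init__(self):
        if not (self.t_b1 < self.t_b2):
            raise ValueError("need t_b1 < t_b2")
        if not (self.s >= 1):
            raise ValueError("steepness factor s must be >= 1")


def perceptual_bias_at(t, spec: GradualChangeSpec):
    """Evaluate the piecewise-linear drifting bias at (global) trial ``t``."""
    t = np.asarray(t, dtype=float)
    frac = (t - spec.t_b1) / (spec.t_b2 - spec.t_b1)
    mid = spec.P0 - (spec.s - 1.0) * spec.P0 / spec.s * frac
    out = np.where(t <= spec.t_b1, spec.P0, np.where(t >= spec.t_b2, spec.P0 / spec.s, mid))
    return out[()]


# ---------------------------------------------------------------------------
# sequential (win-stay / lose-shift) effects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequentialEffectSpec:
    """With probability ``T_se`` a trial's choice ignores the stimulus and
    repeats the previous choice if it was rewarded, else switches."""

    T_se: float = 0.25

    def __post_init__(self):
        if not (0.0 <= self.T_se <= 1.0):
            raise ValueError("T_se must lie in [0, 1]")


def apply_sequential_effect(
    candidate_choice: int,
    prev_choice: int | None,
    prev_reward: bool | None,
    spec: SequentialEffectSpec,
    rng: np.random.Generator,
) -> int:
    """Possibly override a stimulus-driven choice with win-stay/lose-shift."""
    if prev_choice is None or prev_reward is None:
        return candidate_choice
    if rng.random() < spec.T_se:
        return prev_choice if prev_reward else -prev_choice
    return candidate_choice


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------


def simulate_session(
    design: SessionDesign,
    truth: BiasSet,
    S: float | Sequence[float] = 15.0,
    lapses: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | int | None = None,
    decision_bias_fn: Callable[[int], float] | None = None,
    sequential: SequentialEffectSpec | None = None,
    reward_fn: Callable[[TrialRecord], tuple[bool, float]] | None = None,
    t_offset: int = 0,
) -> list[TrialRecord]:
    """Simulate choices for one block-randomized session.

    ``S`` may be a scalar or per-condition (L, N, R) sensory noise.
    ``decision_bias_fn`` overrides the stationary decision bias with a
    function of the global trial index (``t_offset`` + session-local t).
    ``reward_fn`` maps a choice-complete trial to (reward, boundary); it
    is required when simulating sequential effects, which condition on
    the previous trial's reward.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    S_arr = np.broadcast_to(np.asarray(S, dtype=float), (3,))
    if sequential is not None and sequential.T_se > 0 and reward_fn is None:
        raise ValueError("sequential effects need a reward_fn to observe rewards")

    out: list[TrialRecord] = []
    prev_choice: int | None = None
    prev_reward: bool | None = None
    for i, (cond, omega) in enumerate(design.stimulus_order()):
        t = i + 1
        d = truth.D if decision_bias_fn is None else decision_bias_fn(t_offset + t)
        params = PsychometricParams(
            B=truth.perceptual(cond) + d,
            S=float(S_arr[CONDITION_ORDER.index(cond)]),
            lambda1=lapses[0],
            lambda2=lapses[1],
        )
        theta = choice_prob(omega, params)
        choice = 1 if rng.random() < theta else -1
        if sequential is not None:
            choice = apply_sequential_effect(
                choice, prev_choice, prev_reward, sequential, rng
            )
        trial = TrialRecord(t=t, condition=cond, omega=omega, choice=choice)
        if reward_fn is not None:
            rew, boundary = reward_fn(trial)
            trial = TrialRecord(
                t=t, condition=cond, omega=omega, choice=choice,
                reward=rew, boundary_used=boundary,
            )
        out.append(trial)
        prev_choice, prev_reward = choice, trial.reward
    return out


def split_seed(master_seed: int, *stream: int) -> int:
    """Deterministically derive a sub-stream seed below 2**31 from a master
    seed and a tuple of stream indices (experiment / rep / session ...)."""
    mask = (1 << 64) - 1
    h = (int(master_seed) ^ 0x9E3779B97F4A7C15) & mask
    for s in stream:
        h = ((h ^ (int(s) + 1)) * 0xBF58476D1CE4E5B9) & mask
        h ^= h >> 31
    return h % (2**31 - 1)
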