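"""Reward-maximizing agent with adaptable decision criteria.

The agent perceives each stimulus through its perceptual bias and
internal noise, ``omega_hat ~ N(omega - P_k, Sigma_k)``, chooses by MAP
against a per-condition (or shared) decision criterion ``psi_k``
(rightward iff ``omega_hat >= psi_k``), and after reward feedback nudges
the criterion with a temporal-difference rule

    psi_k <- psi_k - alpha * C * (r - q),     q = max(theta_hat, 1 - theta_hat),
    theta_hat = Phi((omega_hat - psi_k) / Sigma_k),

where ``q`` is the agent's predicted reward probability computed from
the PRE-update criterion.  Since |r - q| <= 1, no single trial moves a
criterion by more than ``alpha``.

``run_experiment`` reproduces the strategy-comparison protocol:
independent replicate experiments of many 990-trial sessions, criteria
carried across sessions within a replicate, and a lapse-free ML
psychometric fit per condition per session.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from numba import njit

from .online import OnlineEstimator
from .psychometric import (
    CONDITION_ORDER,
    ConditionLabel,
    TrialRecord,
    fit_empirical_bias,
)
from .reward import RewardStrategy, StrategyKind
from .synthetic_data import (
    DEFAULT_GRID,
    GradualChangeSpec,
    SessionDesign,
    perceptual_bias_at,
    split_seed,
)

_SQRT2 = math.sqrt(2.0)


class CriterionMode(str, enum.Enum):
    INDEPENDENT = "independent"
    SHARED = "shared"


@dataclass(frozen=True)
class RLAgentConfig:
    """Learning rate (deg/trial), internal noise SD (deg) and criterion mode."""

    alpha: float = 0.04
    Sigma: float | tuple[float, float, float] = 16.0
    criterion_mode: CriterionMode = CriterionMode.INDEPENDENT

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if np.any(np.asarray(self.Sigma) <= 0):
            raise ValueError("Sigma must be > 0")

    def sigma_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.Sigma, dtype=float), (3,)).copy()


# ---------------------------------------------------------------------------
# elementary operations (tested directly; the session loop re-implements
# them inside a numba kernel for speed)
# ---------------------------------------------------------------------------


def perceive(omega: float, P_tk: float, Sigma: float, rng: np.random.Generator) -> float:
    """Noisy biased percept: a draw from N(omega - P_tk, Sigma)."""
    if not Sigma > 0:
        raise ValueError("Sigma must be > 0")
    return float(rng.normal(omega - P_tk, Sigma))


def choose_map(omega_hat: float, psi: float) -> int:
    """MAP choice without decision noise: +1 iff the percept is at or right
    of the criterion (tie broken rightward), else -1."""
    return 1 if omega_hat >= psi else -1


def predicted_q(omega_hat: float, psi: float, Sigma: float) -> float:
    """The agent's predicted reward probability, max(theta_hat, 1-theta_hat)."""
    if not Sigma > 0:
        raise ValueError("Sigma must be > 0")
    theta_hat = 0.5 * (1.0 + math.erf((omega_hat - psi) / (Sigma * _SQRT2)))
    return max(theta_hat, 1.0 - theta_hat)


def update_criterion(psi: float, C: int, r: int, q: float, alpha: float) -> float:
    """One temporal-difference step; ``q`` must come from the pre-update psi."""
    if not (0.5 <= q <= 1.0):
        raise ValueError("q must lie in [0.5, 1]")
    return psi - alpha * C * (r - q)


# ---------------------------------------------------------------------------
# numba session kernel (strategies with closed-form reward rules)
# ---------------------------------------------------------------------------

_STRAT_CODE = {
    StrategyKind.VERIDICAL: 0,
    StrategyKind.RANDOM_AMBIGUOUS: 1,
    StrategyKind.ALWAYS_AMBIGUOUS: 2,
    StrategyKind.NEVER_AMBIGUOUS: 3,
    StrategyKind.ORACLE: 4,
}


@njit(cache=True)
def _session_kernel(
    cond_idx, omega, p_truth, psi, shared, sigma, alpha,
    strat, random_prob, seed,
):
    np.random.seed(seed)
    n = cond_idx.shape[0]
    choices = np.empty(n, dtype=np.int64)
    rewards = np.empty(n, dtype=np.int64)
    psi_traj = np.empty((n, 3))
    for i in range(n):
        c = cond_idx[i]
        k = 0 if shared else c
        sig = sigma[c]
        what = omega[i] - p_truth[i] + sig * np.random.normal()
        psi_k = psi[k]
        choice = 1 if what >= psi_k else -1
        # reward rule
        if strat == 0:  # veridical
            rew = (omega[i] < 0.0) if choice == -1 else (omega[i] > 0.0)
        elif strat == 4:  # oracle: boundary at the true perceptual bias
            b = p_truth[i]
            rew = (omega[i] < b) if choice == -1 else (omega[i] > b)
        else:  # ambiguous-band variants, veridical outside the band
            p = p_truth[i]
            lo = p if p < 0.0 else 0.0
            hi = p if p > 0.0 else 0.0
            ambiguous = (c != 1) and (lo <= omega[i] <= hi)
            if ambiguous:
                if strat == 2:
                    rew = True
                elif strat == 3:
                    rew = False
                else:
                    rew = np.random.random() < random_prob
            else:
                rew = (omega[i] < 0.0) if choice == -1 else (omega[i] > 0.0)
        r = 1.0 if rew else 0.0
        theta_hat = 0.5 * (1.0 + math.erf((what - psi_k) / (sig * _SQRT2)))
        q = theta_hat if theta_hat > 1.0 - theta_hat else 1.0 - theta_hat
        psi[k] = psi_k - alpha * choice * (r - q)
        choices[i] = choice
        rewards[i] = 1 if rew else 0
        psi_traj[i, 0] = psi[0]
        psi_traj[i, 1] = psi[1 if not shared else 0]
        psi_traj[i, 2] = psi[2 if not shared else 0]
    return choices, rewards, psi_traj


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthSchedule:
    """Ground-truth perceptual biases, possibly drifting across the
    experiment's global trial index (session boundaries do not reset t)."""

    P_L: float = 20.0
    P_R: float = -10.0
    drift_L: GradualChangeSpec | None = None
    drift_R: GradualChangeSpec | None = None

    def at(self, t_global) -> tuple[np.ndarray, np.ndarray]:
        t_global = np.asarray(t_global)
        pl = (np.full(t_global.shape, self.P_L) if self.drift_L is None
              else np.asarray(perceptual_bias_at(t_global, self.drift_L)))
        pr = (np.full(t_global.shape, self.P_R) if self.drift_R is None
              else np.asarray(perceptual_bias_at(t_global, self.drift_R)))
        return pl, pr


@dataclass
class RLExperimentResult:
    """Per-session outcomes of an RL strategy experiment."""

    strategy: str
    n_reps: int
    n_sessions: int
    #: fitted empirical bias, shape (reps, sessions, 3) ordered (L, N, R)
    B_hat: np.ndarray
    S_hat: np.ndarray
    #: decision criteria at session end and their within-session means
    psi_end: np.ndarray
    psi_mean: np.ndarray
    #: perceptual-bias estimates used for rewards (estimated strategy only)
    est_P: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep in range(self.n_reps):
            for s in range(self.n_sessions):
                for ci, cond in enumerate(CONDITION_ORDER):
                    rows.append({
                        "rep": rep, "session": s + 1, "condition": cond.value,
                        "psi_end": self.psi_end[rep, s, ci],
                        "psi_mean": self.psi_mean[rep, s, ci],
                        "B_hat": self.B_hat[rep, s, ci],
                        "S_hat": self.S_hat[rep, s, ci],
                    })
        return pd.DataFrame(rows)


def _fit_session(cond_idx, omega, choices):
    B = np.empty(3)
    S = np.empty(3)
    for ci in range(3):
        m = cond_idx == ci
        fit = fit_empirical_bias(omegas=omega[m], choices=choices[m])
        B[ci], S[ci] = fit.B, fit.S
    return B, S


def run_experiment(
    strategy: RewardStrategy,
    agent_cfg: RLAgentConfig = RLAgentConfig(),
    truth: TruthSchedule = TruthSchedule(),
    grid=DEFAULT_GRID,
    n_blocks: int = 30,
    n_sessions: int = 50,
    n_reps: int = 10,
    master_seed: int = 0,
    symmetric_grid: bool = False,
    estimator_factory: Callable[[int, int], OnlineEstimator] | None = None,
    on_session_end: Callable[[int, int, OnlineEstimator], None] | None = None,
    fit_sessions: bool = True,
) -> RLExperimentResult:
    """Simulate replicate training experiments under one reward strategy.

    ``symmetric_grid`` translates each condition's stimulus grid by that
    condition's true perceptual bias (evaluated at the session's first
    trial), removing the stimulus-range asymmetry around the subjective
    boundary.  For the estimated strategy, ``estimator_factory(rep,
    session)`` must supply a fresh :class:`OnlineEstimator` per session
    (it controls priors, refit cadence and draw counts).
    """
    if strategy.kind is StrategyKind.ESTIMATED and estimator_factory is None:
        raise ValueError("estimated strategy needs an estimator_factory")

    sigma = agent_cfg.sigma_array()
    shared = agent_cfg.criterion_mode is CriterionMode.SHARED
    n_per = n_blocks * len(grid) * 3
    shape = (n_reps, n_sessions, 3)
    B_hat = np.full(shape, np.nan)
    S_hat = np.full(shape, np.nan)
    psi_end = np.zeros(shape)
    psi_mean = np.zeros(shape)
    est_P = (np.full((n_reps, n_sessions, 2), np.nan)
             if strategy.kind is StrategyKind.ESTIMATED else None)

    for rep in range(n_reps):
        psi = np.zeros(3)
        for s in range(n_sessions):
            t0 = s * n_per
            pl0, pr0 = truth.at(t0 + 1)
            offsets = {}
            if symmetric_grid:
                offsets = {ConditionLabel.L: float(pl0), ConditionLabel.R: float(pr0)}
            design = SessionDesign(
                grid=tuple(grid), n_blocks=n_blocks,
                seed=split_seed(master_seed, rep, s, 0), grid_offsets=offsets,
            )
            order = design.stimulus_order()
            cond_idx = np.array(
                [CONDITION_ORDER.index(c) for c, _ in order], dtype=np.int64
            )
            omega = np.array([om for _, om in order])
            tg = t0 + 1 + np.arange(n_per)
            pl, pr = truth.at(tg)
            p_truth = np.where(cond_idx == 0, pl, np.where(cond_idx == 2, pr, 0.0))

            if strategy.kind is StrategyKind.ESTIMATED:
                choices, psi_traj, est = _run_estimated_session(
                    cond_idx, omega, p_truth, psi, shared, sigma,
                    agent_cfg.alpha, estimator_factory(rep, s),
                    split_seed(master_seed, rep, s, 1),
                )
                est_P[rep, s, 0] = est.last_posterior.means["P_L"] if est.last_posterior else np.nan
                est_P[rep, s, 1] = est.last_posterior.means["P_R"] if est.last_posterior else np.nan
                if on_session_end is not None:
                    on_session_end(rep, s, est)
            else:
                choices, _, psi_traj = _session_kernel(
                    cond_idx, omega, p_truth, psi, shared, sigma,
                    agent_cfg.alpha, _STRAT_CODE[strategy.kind],
                    strategy.random_prob, split_seed(master_seed, rep, s, 1),
                )
            psi_end[rep, s] = psi_traj[-1]
            psi_mean[rep, s] = psi_traj.mean(axis=0)
            if fit_sessions:
                B_hat[rep, s], S_hat[rep, s] = _fit_session(cond_idx, omega, choices)

    return RLExperimentResult(
        strategy=strategy.kind.value, n_reps=n_reps, n_sessions=n_sessions,
        B_hat=B_hat, S_hat=S_hat, psi_end=psi_end, psi_mean=psi_mean, est_P=est_P,
    )


def _run_estimated_session(
    cond_idx, omega, p_truth, psi, shared, sigma, alpha,
    estimator: OnlineEstimator, seed: int,
):
    """Python-level per-trial loop for the estimated strategy (the reward
    boundary changes with each online refit, so the trial loop and the
    estimator must interleave)."""
    rng = np.random.default_rng(seed)
    n = cond_idx.shape[0]
    choices = np.empty(n, dtype=np.int64)
    psi_traj = np.empty((n, 3))
    for i in range(n):
        c = int(cond_idx[i])
        k = 0 if shared else c
        sig = sigma[c]
        what = float(rng.normal(omega[i] - p_truth[i], sig))
        psi_k = psi[k]
        choice = choose_map(what, psi_k)
        cond = CONDITION_ORDER[c]
        trial = TrialRecord(t=i + 1, condition=cond, omega=float(omega[i]), choice=choice)
        estimator.record(trial)
        rew, boundary = estimator.reward_for(trial)
        estimator.trials[-1] = TrialRecord(
            t=i + 1, condition=cond, omega=float(omega[i]), choice=choice,
            reward=rew, boundary_used=boundary,
        )
        q = predicted_q(what, psi_k, sig)
        psi[k] = update_criterion(psi_k, choice, int(rew), q, alpha)
        choices[i] = choice
        psi_traj[i, 0] = psi[0]
        psi_traj[i, 1] = psi[1 if not shared else 0]
        psi_traj[i, 2] = psi[2 if not shared else 0]
    return choices, psi_traj, estimator
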