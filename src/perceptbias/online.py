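"""Trial-by-trial posterior updating and reward-boundary tracking.

The online loop mirrors the in-session procedure used for animal
training: boundaries start at the prior means of the perceptual biases;
after the first 33 trials (one pass through all unique stimuli) the
posterior is recomputed every ``refit_cadence`` trials, warm-starting
each refit from the previous chain state; after every recorded trial the
boundaries move toward the latest posterior-mean proposal by at most
``max_step`` degrees (1 deg = 1% of the stimulus range by default), so
the boundary trajectory is 1-Lipschitz in the trial index.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

from . import reward as rew
from .inference import PosteriorSummary, PriorSpec, SamplerConfig, WarmState, fit_posterior
from .psychometric import ConditionLabel, TrialRecord


@dataclass
class TracePoint:
    """One per-trial log entry of the online loop."""

    t: int
    boundary_L: float
    boundary_R: float
    refit: bool
    P_L: float | None = None
    P_R: float | None = None
    D: float | None = None
    refit_seconds: float | None = None


@dataclass
class OnlineEstimator:
    """Streaming bias estimator + reward-boundary tracker for one session."""

    priors: PriorSpec
    cfg: SamplerConfig = field(default_factory=SamplerConfig)
    start_after: int = 33
    max_step: float = 1.0
    warm_burn_in: int = 100
    latency_budget: float | None = None  # seconds; warn on slower refits

    def __post_init__(self):
        self.trials: list[TrialRecord] = []
        self.state: rew.RewardState = rew.initial_state(self.priors, self.max_step)
        self._warm: WarmState | None = None
        self.last_posterior: PosteriorSummary | None = None
        self._proposal_L = self.priors.P_L.mean
        self._proposal_R = self.priors.P_R.mean
        self.trace: list[TracePoint] = []

    def boundary(self, condition: ConditionLabel) -> float:
        return self.state.boundary(condition)

    def reward_for(self, trial: TrialRecord) -> tuple[bool, float]:
        """Reward decision for a choice-complete trial at the current boundary."""
        b = self.boundary(trial.condition)
        return rew.decide_reward(trial.choice, trial.omega, b), b

    def record(self, trial: TrialRecord) -> TracePoint:
        """Ingest one trial, refit if due, and advance the boundaries."""
        self.trials.append(trial)
        t = len(self.trials)
        did_refit = False
        elapsed = None
        if t >= self.start_after and (t - self.start_after) % self.cfg.refit_cadence == 0:
            t0 = time.perf_counter()
            self._refit(t)
            elapsed = time.perf_counter() - t0
            did_refit = True
            if self.latency_budget is not None and elapsed > self.latency_budget:
                warnings.warn(
                    f"online refit at t={t} took {elapsed:.2f}s "
                    f"(> budget {self.latency_budget:.2f}s)",
                    RuntimeWarning,
                )
        self.state = rew.update_boundary(
            self.state, self._proposal_L, self._proposal_R, t
        )
        point = TracePoint(
            t=t,
            boundary_L=self.state.boundary_L,
            boundary_R=self.state.boundary_R,
            refit=did_refit,
            P_L=self.last_posterior.means["P_L"] if self.last_posterior else None,
            P_R=self.last_posterior.means["P_R"] if self.last_posterior else None,
            D=self.last_posterior.means["D"] if self.last_posterior else None,
            refit_seconds=elapsed,
        )
        self.trace.append(point)
        return point

    def _refit(self, t: int) -> None:
        if self._warm is not None:
            cfg = replace(
                self.cfg,
                burn_in=min(self.warm_burn_in, self.cfg.n_draws - 1),
                seed=(self.cfg.seed + t) % (2**31 - 1),
                compute_diagnostics=False,
            )
        else:
            cfg = replace(
                self.cfg,
                seed=(self.cfg.seed + t) % (2**31 - 1),
                compute_diagnostics=False,
            )
        summary = fit_posterior(self.trials, self.priors, cfg, warm=self._warm)
        if self.cfg.warm_start:
            self._warm = summary.warm_state
        self.last_posterior = summary
        self._proposal_L = summary.means["P_L"]
        self._proposal_R = summary.means["P_R"]


def run_online_session(
    trials,
    priors: PriorSpec,
    cfg: SamplerConfig = SamplerConfig(),
    max_step: float = 1.0,
    start_after: int = 33,
    latency_budget: float | None = None,
) -> OnlineEstimator:
    """Replay a recorded (or synthetic) trial sequence through the online
    loop, recomputing reward decisions without overwriting recorded ones."""
    est = OnlineEstimator(
        priors=priors, cfg=cfg, start_after=start_after,
        max_step=max_step, latency_budget=latency_budget,
    )
    for tr in trials:
        # per the allocation loop: the posterior is updated with the current
        # trial's choice first, then the reward is decided at the (possibly
        # just-moved) boundary
        est.record(TrialRecord(t=tr.t, condition=tr.condition,
                               omega=tr.omega, choice=tr.choice))
        rew_flag, boundary = est.reward_for(tr)
        est.trials[-1] = TrialRecord(
            t=tr.t, condition=tr.condition, omega=tr.omega,
            choice=tr.choice, reward=rew_flag, boundary_used=boundary,
        )
    return est
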