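"""Observer/decision model for 2AFC direction discrimination.

The probability of a rightward choice follows a cumulative-Gaussian
psychometric function with lapse asymptotes,

    theta(omega) = lambda1 + (1 - lambda1 - lambda2) * Phi((omega - B) / S),

where ``B`` is the empirical bias (horizontal shift, deg), ``S`` the
sensory noise (slope, deg) and ``lambda1``/``lambda2`` the lower/upper
lapse rates.  The empirical bias in each contextual condition decomposes
into a condition-specific perceptual bias plus a decision bias shared
across the interleaved conditions:

    B_L = P_L + D,   B_N = D,   B_R = P_R + D.

Angles are plain degrees with no wraparound: the task range (about
+/-40 deg around the reference) is far from +/-180, so circular
statistics are deliberately out of scope.  Positive omega and positive
biases mean "rightward of the reference".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr


class ConditionLabel(str, enum.Enum):
    """Contextual condition of a trial: leftward/neutral/rightward self-motion."""

    L = "L"
    N = "N"
    R = "R"

    @classmethod
    def from_str(cls, s: str) -> "ConditionLabel":
        try:
            return cls(s)
        except ValueError:
            raise ValueError(f"unknown condition label {s!r}; expected one of L, N, R")


#: fixed ordering used for array-coded conditions everywhere in the package
CONDITION_ORDER: tuple[ConditionLabel, ...] = (
    ConditionLabel.L,
    ConditionLabel.N,
    ConditionLabel.R,
)

CONDITION_INDEX: dict[ConditionLabel, int] = {c: i for i, c in enumerate(CONDITION_ORDER)}


@dataclass(frozen=True)
class TrialRecord:
    """One 2AFC trial.

    Parameters
    ----------
    t : int
        1-based, session-local trial index (strictly increasing).
    condition : ConditionLabel
        Contextual condition of the trial.
    omega : float
        Stimulus direction in degrees; positive = rightward of reference.
    choice : int
        +1 for a rightward choice, -1 for leftward.
    reward : bool or None
        Whether a reward was delivered (None if not yet assigned).
    boundary_used : float or None
        Reward boundary (deg) in effect when the reward was decided.
    """

    t: int
    condition: ConditionLabel
    omega: float
    choice: int
    reward: bool | None = None
    boundary_used: float | None = None

    def __post_init__(self):
        if self.t < 1:
            raise ValueError("trial index t must be >= 1")
        if not math.isfinite(self.omega):
            raise ValueError("omega must be finite")
        if self.choice not in (-1, 1):
            raise ValueError("choice must be +1 (right) or -1 (left)")
        if self.reward is not None and self.boundary_used is None:
            raise ValueError("a rewarded trial must record the boundary used")


def choice_to_pm1(choice: str) -> int:
    """Map 'left'/'right' to the -1/+1 coding used by the Bernoulli and RL models."""
    if choice == "right":
        return 1
    if choice == "left":
        return -1
    raise ValueError(f"unknown choice {choice!r}")


def choice_to_str(choice: int) -> str:
    """Inverse of :func:`choice_to_pm1`."""
    if choice == 1:
        return "right"
    if choice == -1:
        return "left"
    raise ValueError(f"choice code must be +/-1, got {choice!r}")


@dataclass(frozen=True)
class PsychometricParams:
    """Cumulative-Gaussian psychometric parameters for one condition."""

    B: float
    S: float
    lambda1: float = 0.0
    lambda2: float = 0.0

    def __post_init__(self):
        if not (self.S > 0):
            raise ValueError("sensory noise S must be > 0")
        if not (0 <= self.lambda1 < 1 and 0 <= self.lambda2 < 1):
            raise ValueError("lapse rates must lie in [0, 1)")
        if self.lambda1 + self.lambda2 >= 1:
            raise ValueError("lambda1 + lambda2 must be < 1")


@dataclass(frozen=True)
class BiasSet:
    """Perceptual biases (P_L, P_R) and the shared decision bias D, in degrees."""

    P_L: float
    P_R: float
    D: float = 0.0

    def __post_init__(self):
        for v in (self.P_L, self.P_R, self.D):
            if not math.isfinite(v):
                raise ValueError("biases must be finite")

    def perceptual(self, condition: ConditionLabel) -> float:
        """Perceptual bias of a condition (neutral has none by definition)."""
        if condition is ConditionLabel.L:
            return self.P_L
        if condition is ConditionLabel.R:
            return self.P_R
        return 0.0


def empirical_biases(biases: BiasSet) -> tuple[float, float, float]:
    """Empirical biases (B_L, B_N, B_R) implied by a bias decomposition.

    The decision bias shifts all conditions alike; each contextual
    condition adds its own perceptual bias on top.
    """
    return (biases.P_L + biases.D, biases.D, biases.P_R + biases.D)


def choice_prob(omega, params: PsychometricParams):
    """Probability of a rightward choice at stimulus direction ``omega`` (deg).

    Accepts a scalar or array ``omega``; returns the same shape.
    """
    omega = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ValueError("omega must be finite")
    phi = ndtr((omega - params.B) / params.S)
    out = params.lambda1 + (1.0 - params.lambda1 - params.lambda2) * phi
    return out if out.ndim else float(out)


def sample_choice(theta, rng: np.random.Generator):
    """Draw a Bernoulli choice: +1 (right) with probability ``theta``, else -1."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0) or np.any(theta > 1):
        raise ValueError("theta must lie in [0, 1]")
    draw = rng.random(theta.shape) < theta
    out = np.where(draw, 1, -1)
    return out if out.ndim else int(out)


# ---------------------------------------------------------------------------
# per-condition ML probit fit (lapse-free)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmpiricalBiasFit:
    """Result of a lapse-free maximum-likelihood cumulative-Gaussian fit."""

    B: float
    S: float
    loglik: float
    identifiable: bool = True


def aggregate_counts(
    omegas: Sequence[float], choices: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse raw trials into (unique omega, n trials, n rightward choices)."""
    om = np.asarray(omegas, dtype=float)
    ch = np.asarray(choices)
    uniq, inv = np.unique(om, return_inverse=True)
    n = np.bincount(inv, minlength=uniq.size).astype(float)
    k = np.bincount(inv, weights=(ch == 1).astype(float), minlength=uniq.size)
    return uniq, n, k


def _probit_negloglik(params, x, n, k):
    b, log_s = params
    s = math.exp(log_s)
    p = ndtr((x - b) / s)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def fit_empirical_bias(
    trials: Iterable[TrialRecord] | None = None,
    *,
    omegas: Sequence[float] | None = None,
    choices: Sequence[int] | None = None,
) -> EmpiricalBiasFit:
    """Lapse-free ML probit fit of (B, S) for one condition's trials.

    Multi-start optimization (starts at the grid quantiles of the choice
    split) with a deterministic tie-break: on (numerically) equal
    likelihood the lowest fitted bias wins.  If every choice is identical
    the bias is not identifiable; the fit then returns the data boundary
    (outermost stimulus on the observed side) flagged ``identifiable=False``.
    """
    if trials is not None:
        trials = list(trials)
        omegas = [tr.omega for tr in trials]
        choices = [tr.choice for tr in trials]
    if omegas is None or choices is None:
        raise ValueError("provide either trials or (omegas, choices)")
    x, n, k = aggregate_counts(omegas, choices)
    if x.size < 2:
        raise ValueError("need >= 2 distinct stimulus values")

    frac_right = k.sum() / n.sum()
    if frac_right in (0.0, 1.0):
        # all-left -> boundary beyond the largest stimulus; all-right -> beyond smallest
        b = float(x.max()) if frac_right == 0.0 else float(x.min())
        return EmpiricalBiasFit(B=b, S=float(np.ptp(x)), loglik=0.0, identifiable=False)

    span = float(np.ptp(x))
    # starts: crossing-point quantiles of the observed right-choice fraction
    p_hat = k / n
    crossing = float(np.interp(0.5, np.clip(p_hat, 0, 1), x)) if np.any(p_hat >= 0.5) else 0.0
    starts = [
        (crossing, math.log(span / 4)),
        (float(np.quantile(x, 0.25)), math.log(span / 2)),
        (float(np.quantile(x, 0.75)), math.log(span / 8)),
        (0.0, math.log(max(span / 4, 1e-3))),
    ]
    best: tuple[float, float, float] | None = None
    for x0 in starts:
        res = minimize(_probit_negloglik, x0, args=(x, n, k), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        cand = (float(res.fun), float(res.x[0]), float(res.x[1]))
        if best is None or cand[0] < best[0] - 1e-9 or (
            abs(cand[0] - best[0]) <= 1e-9 and cand[1] < best[1]
        ):
            best = cand
    nll, b, log_s = best
    return EmpiricalBiasFit(B=b, S=math.exp(log_s), loglik=-nll)
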