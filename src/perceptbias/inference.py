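"""Hierarchical Bayesian estimation of perceptual and decision biases.

The generative model for a session with interleaved contextual
conditions ``k in {L, N, R}``:

    C_t ~ Bernoulli(theta_{t,k})
    theta_{t,k} = lambda1_k + (1 - lambda1_k - lambda2_k) Phi((omega_t - B_k)/S_k)
    B_L = P_L + D,  B_N = D,  B_R = P_R + D
    P_L ~ N(P0_L, tau_PL),  P_R ~ N(P0_R, tau_PR),  D ~ N(D0, tau_D)
    S_k ~ Gamma(alpha, beta)   (beta is a RATE; default Gamma(8, 0.5), mean 16 deg)
    lambda_{1,k}, lambda_{2,k} ~ Beta(gamma, eps)   (default Beta(1, 10))

Posteriors are computed by an in-package componentwise adaptive
Metropolis sampler (see ``_mcmc``).  A flat variant replaces the three
bias priors with Uniform(-180, 180), which makes the posterior mean an
(regularized) maximum-likelihood estimate.  A "conventional" baseline
fits each condition independently with a prior only on its empirical
bias and recovers perceptual biases by subtraction; it mimics what an
off-the-shelf psychometric-fitting package with empirical-bias priors
can do, and serves as the comparison method in the validation suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from ._mcmc import NPAR, run_chain
from .psychometric import (
    CONDITION_INDEX,
    CONDITION_ORDER,
    ConditionLabel,
    TrialRecord,
)

PARAM_NAMES = (
    "P_L", "P_R", "D",
    "S_L", "S_N", "S_R",
    "lambda1_L", "lambda1_N", "lambda1_R",
    "lambda2_L", "lambda2_N", "lambda2_R",
)


class Gaussian(NamedTuple):
    """A univariate Gaussian prior, mean and SD in degrees."""

    mean: float
    sd: float


def convolve_bias_priors(perc: Gaussian, dec: Gaussian) -> Gaussian:
    """Prior over an empirical bias implied by independent perceptual and
    decision-bias priors: the closed-form sum of two independent Gaussians."""
    return Gaussian(perc.mean + dec.mean, float(np.hypot(perc.sd, dec.sd)))


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the bias model.

    ``S_shape``/``S_rate`` may be scalars (shared across conditions, the
    default and what was used in the source experiments) or length-3
    sequences ordered (L, N, R).  ``flat=True`` replaces the three bias
    priors with Uniform(-180, 180) and ignores the bias means/SDs.
    ``fix_S`` / ``fix_lapses`` clamp those parameters instead of sampling
    them (used by validation oracles and lapse-free simulations).
    """

    P_L: Gaussian = Gaussian(0.0, 5.0)
    P_R: Gaussian = Gaussian(0.0, 5.0)
    D: Gaussian = Gaussian(0.0, 10.0)
    S_shape: float | Sequence[float] = 8.0
    S_rate: float | Sequence[float] = 0.5
    lapse_a: float = 1.0
    lapse_b: float = 10.0
    flat: bool = False
    fix_S: tuple[float, float, float] | None = None
    fix_lapses: bool = False

    def __post_init__(self):
        for g in (self.P_L, self.P_R, self.D):
            if not (g.sd > 0):
                raise ValueError("prior SDs must be > 0")
        if not (self.lapse_a > 0 and self.lapse_b > 0):
            raise ValueError("Beta prior parameters must be > 0")
        for v in np.atleast_1d(self.S_shape).tolist() + np.atleast_1d(self.S_rate).tolist():
            if not (v > 0):
                raise ValueError("Gamma prior parameters must be > 0")

    def _s_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        shape = np.broadcast_to(np.asarray(self.S_shape, dtype=float), (3,)).copy()
        rate = np.broadcast_to(np.asarray(self.S_rate, dtype=float), (3,)).copy()
        return shape, rate

    @classmethod
    def flat_priors(cls, **kw) -> "PriorSpec":
        return cls(flat=True, **kw)

    def to_dict(self) -> dict:
        shape, rate = self._s_arrays()
        return {
            "P_L": {"mean": self.P_L.mean, "sd": self.P_L.sd},
            "P_R": {"mean": self.P_R.mean, "sd": self.P_R.sd},
            "D": {"mean": self.D.mean, "sd": self.D.sd},
            "S_shape": shape.tolist(),
            "S_rate": rate.tolist(),
            "lapse_a": self.lapse_a,
            "lapse_b": self.lapse_b,
            "flat": self.flat,
            "fix_S": list(self.fix_S) if self.fix_S is not None else None,
            "fix_lapses": self.fix_lapses,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        g = lambda key: Gaussian(d[key]["mean"], d[key]["sd"])
        return cls(
            P_L=g("P_L"), P_R=g("P_R"), D=g("D"),
            S_shape=d.get("S_shape", 8.0), S_rate=d.get("S_rate", 0.5),
            lapse_a=d.get("lapse_a", 1.0), lapse_b=d.get("lapse_b", 10.0),
            flat=d.get("flat", False),
            fix_S=tuple(d["fix_S"]) if d.get("fix_S") else None,
            fix_lapses=d.get("fix_lapses", False),
        )


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC settings; defaults mirror the online procedure (5000 draws,
    first 2500 discarded, single chain, refit after every trial)."""

    n_draws: int = 5000
    burn_in: int = 2500
    seed: int = 0
    n_chains: int = 1
    refit_cadence: int = 1
    warm_start: bool = True
    compute_diagnostics: bool = True
    rhat_threshold: float = 1.05

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_draws):
            raise ValueError("need 0 <= burn_in < n_draws")
        if self.n_chains < 1 or self.refit_cadence < 1:
            raise ValueError("n_chains and refit_cadence must be >= 1")


@dataclass
class WarmState:
    """Carry-over between online refits: last chain state and tuned scales."""

    params: np.ndarray
    log_scales: np.ndarray


@dataclass
class PosteriorSummary:
    """Posterior draws and summaries for one fit of the bias model."""

    samples: dict[str, np.ndarray]
    means: dict[str, float]
    sds: dict[str, float]
    ci68: dict[str, tuple[float, float]]
    ci95: dict[str, tuple[float, float]]
    n_trials_used: int
    seed: int
    diagnostics: dict[str, dict[str, float]] = field(default_factory=dict)
    converged: bool = True
    warm_state: WarmState | None = None

    def mean(self, name: str) -> float:
        return self.means[name]

    def to_json(self, path=None) -> str:
        payload = {
            "means": self.means,
            "sds": self.sds,
            "ci68": {k: list(v) for k, v in self.ci68.items()},
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "n_trials_used": self.n_trials_used,
            "seed": self.seed,
            "diagnostics": self.diagnostics,
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def trials_to_cells(
    trials: Iterable[TrialRecord],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Aggregate trials into (condition, stimulus) cells with binomial counts."""
    cond, omega, choice = [], [], []
    for tr in trials:
        cond.append(CONDITION_INDEX[tr.condition])
        omega.append(tr.omega)
        choice.append(tr.choice)
    if not cond:
        raise ValueError("trials must be nonempty")
    cond = np.asarray(cond, dtype=np.int64)
    omega = np.asarray(omega, dtype=float)
    right = (np.asarray(choice) == 1).astype(float)
    key = cond * 1_000_003 + np.round(omega * 1e6).astype(np.int64)
    _, idx, inv = np.unique(key, return_index=True, return_inverse=True)
    n = np.bincount(inv).astype(float)
    k = np.bincount(inv, weights=right)
    return cond[idx], omega[idx], n, k, int(right.size)


def _prior_arrays(priors: PriorSpec):
    bias_mean = np.array([priors.P_L.mean, priors.P_R.mean, priors.D.mean])
    bias_sd = np.array([priors.P_L.sd, priors.P_R.sd, priors.D.sd])
    shape, rate = priors._s_arrays()
    fix_S = priors.fix_S is not None
    fixed_S = np.asarray(priors.fix_S if fix_S else (15.0, 15.0, 15.0), dtype=float)
    return bias_mean, bias_sd, shape, rate, fix_S, fixed_S


def _initial_state(priors: PriorSpec) -> np.ndarray:
    """Chain initialization at the prior means (design choice)."""
    init = np.zeros(NPAR)
    if not priors.flat:
        init[0], init[1], init[2] = priors.P_L.mean, priors.P_R.mean, priors.D.mean
    shape, rate = priors._s_arrays()
    init[3:6] = np.log(shape / rate)
    # prior-mean lapse on the logit scale
    m = priors.lapse_a / (priors.lapse_a + priors.lapse_b)
    init[6:12] = np.log(m / (1 - m))
    return init


def _free_mask(priors: PriorSpec) -> np.ndarray:
    mask = np.ones(NPAR, dtype=np.bool_)
    if priors.fix_S is not None:
        mask[3:6] = False
    if priors.fix_lapses:
        mask[6:12] = False
    return mask


def _summarize(draws: np.ndarray, priors: PriorSpec) -> dict[str, np.ndarray]:
    samples: dict[str, np.ndarray] = {}
    samples["P_L"] = draws[:, 0]
    samples["P_R"] = draws[:, 1]
    samples["D"] = draws[:, 2]
    if priors.fix_S is not None:
        for i, c in enumerate("LNR"):
            samples[f"S_{c}"] = np.full(draws.shape[0], priors.fix_S[i])
    else:
        for i, c in enumerate("LNR"):
            samples[f"S_{c}"] = np.exp(draws[:, 3 + i])
    for i, c in enumerate("LNR"):
        if priors.fix_lapses:
            samples[f"lambda1_{c}"] = np.zeros(draws.shape[0])
            samples[f"lambda2_{c}"] = np.zeros(draws.shape[0])
        else:
            samples[f"lambda1_{c}"] = 1 / (1 + np.exp(-draws[:, 6 + i]))
            samples[f"lambda2_{c}"] = 1 / (1 + np.exp(-draws[:, 9 + i]))
    # empirical biases are deterministic transforms; B_N is identically D
    samples["B_L"] = samples["P_L"] + samples["D"]
    samples["B_N"] = samples["D"]
    samples["B_R"] = samples["P_R"] + samples["D"]
    return samples


def _diagnostics(per_chain: list[np.ndarray], names: Sequence[str], priors: PriorSpec):
    """Split-chain rank-normalized R-hat and bulk ESS via arviz."""
    import arviz as az  # deferred: slow import, not needed on the online path

    free = [n for n, m in zip(PARAM_NAMES, _free_mask(priors)) if m]
    half = per_chain[0].shape[0] // 2
    stacked = {}
    for j, name in enumerate(PARAM_NAMES):
        if name not in free:
            continue
        # split each chain in half so the split-chain diagnostic works even
        # for the single-chain online default
        stacked[name] = np.stack(
            [c[:half, j] for c in per_chain] + [c[half : 2 * half, j] for c in per_chain]
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(stacked)
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    out = {}
    for name in stacked:
        out[name] = {
            "rhat": float(rhat[name].values),
            "ess": float(ess[name].values),
        }
    return out


def _fit_cells(
    cells,
    n_trials: int,
    priors: PriorSpec,
    cfg: SamplerConfig,
    warm: WarmState | None = None,
) -> PosteriorSummary:
    cell_cond, cell_omega, cell_n, cell_k = cells
    bias_mean, bias_sd, shape, rate, fix_S, fixed_S = _prior_arrays(priors)
    mask = _free_mask(priors)

    if warm is not None:
        init = warm.params.copy()
        log_scales = warm.log_scales.copy()
        adapt = False
    else:
        init = _initial_state(priors)
        log_scales = np.full(NPAR, np.log(1.0))
        log_scales[3:6] = np.log(0.15)
        log_scales[6:12] = np.log(0.8)
        if priors.flat:
            log_scales[:3] = np.log(4.0)
        adapt = True

    per_chain = []
    final_state = None
    final_scales = None
    for chain in range(cfg.n_chains):
        draws, state, scales, _ = run_chain(
            init, cfg.n_draws, cfg.burn_in, log_scales, mask,
            cell_cond, cell_omega, cell_n, cell_k,
            bias_mean, bias_sd, priors.flat,
            shape, rate, priors.lapse_a, priors.lapse_b,
            priors.fix_lapses, fix_S, fixed_S,
            (cfg.seed + 7919 * chain) % (2**31 - 1), adapt,
        )
        per_chain.append(draws)
        final_state, final_scales = state, scales

    all_draws = np.concatenate(per_chain, axis=0)
    samples = _summarize(all_draws, priors)
    means = {k: float(np.mean(v)) for k, v in samples.items()}
    sds = {k: float(np.std(v)) for k, v in samples.items()}
    ci68 = {k: (float(np.quantile(v, 0.16)), float(np.quantile(v, 0.84)))
            for k, v in samples.items()}
    ci95 = {k: (float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))
            for k, v in samples.items()}

    diagnostics: dict = {}
    converged = True
    if cfg.compute_diagnostics:
        diagnostics = _diagnostics(per_chain, PARAM_NAMES, priors)
        worst = max((d["rhat"] for d in diagnostics.values()), default=1.0)
        converged = bool(worst <= cfg.rhat_threshold)
        if not converged:
            warnings.warn(
                f"MCMC convergence diagnostic exceeded threshold "
                f"(max split-Rhat {worst:.3f} > {cfg.rhat_threshold}); "
                "summary flagged non-converged",
                RuntimeWarning,
            )
    return PosteriorSummary(
        samples=samples, means=means, sds=sds, ci68=ci68, ci95=ci95,
        n_trials_used=n_trials, seed=cfg.seed,
        diagnostics=diagnostics, converged=converged,
        warm_state=WarmState(final_state, final_scales),
    )


def fit_posterior(
    trials: Iterable[TrialRecord],
    priors: PriorSpec,
    cfg: SamplerConfig = SamplerConfig(),
    warm: WarmState | None = None,
) -> PosteriorSummary:
    """Posterior over (P_L, P_R, D, S_k, lambdas) given one session's trials.

    With zero neutral trials the decision bias is identified only through
    the prior; a warning is emitted rather than refusing to fit.
    """
    cond, omega, n, k, n_trials = trials_to_cells(trials)
    if not np.any(cond == CONDITION_INDEX[ConditionLabel.N]):
        warnings.warn(
            "no neutral-condition trials: the decision bias posterior is "
            "prior-driven and perceptual biases absorb any shared shift",
            RuntimeWarning,
        )
    return _fit_cells((cond, omega, n, k), n_trials, priors, cfg, warm)


def fit_flat(
    trials: Iterable[TrialRecord],
    cfg: SamplerConfig = SamplerConfig(),
    priors: PriorSpec | None = None,
) -> PosteriorSummary:
    """Maximum-likelihood-style fit: Uniform(-180, 180) priors on all biases.

    The noise and lapse priors are retained (they regularize parameters
    the flat-prior comparison is not about).
    """
    base = priors if priors is not None else PriorSpec()
    return fit_posterior(trials, replace(base, flat=True), cfg)


# ---------------------------------------------------------------------------
# conventional baseline: per-condition fits with empirical-bias priors
# ---------------------------------------------------------------------------


@dataclass
class BaselineSummary:
    """Per-condition empirical-bias posteriors plus recovered perceptual biases.

    The recovery treats the neutral empirical bias as the decision bias:
    ``P_L = B_L - B_N`` and ``P_R = B_R - B_N``, with the subtraction done
    on independently sampled (shuffled) chains so that variances add.
    """

    samples: dict[str, np.ndarray]
    means: dict[str, float]
    sds: dict[str, float]
    n_trials_used: int
    per_condition: dict[str, PosteriorSummary]


def fit_baseline_empirical(
    trials: Iterable[TrialRecord],
    empirical_priors: dict[ConditionLabel, Gaussian],
    cfg: SamplerConfig = SamplerConfig(),
    base_priors: PriorSpec | None = None,
) -> BaselineSummary:
    """Fit each condition independently with a prior only on its empirical bias.

    ``empirical_priors`` would typically be built with
    :func:`convolve_bias_priors` so that the implied empirical-bias priors
    match the full model's.  No cross-condition tying is used.
    """
    trials = list(trials)
    base = base_priors if base_priors is not None else PriorSpec()
    per_condition: dict[str, PosteriorSummary] = {}
    n_total = 0
    for cond in CONDITION_ORDER:
        sub = [tr for tr in trials if tr.condition is cond]
        if not sub:
            raise ValueError(f"no trials in condition {cond.value}")
        n_total += len(sub)
        # reuse the full-model machinery on a single condition by mapping its
        # cells onto the neutral slot: B_N = D carries the empirical bias,
        # with the supplied empirical prior on D and P_L, P_R clamped at 0.
        cells = trials_to_cells(
            TrialRecord(tr.t, ConditionLabel.N, tr.omega, tr.choice) for tr in sub
        )
        pri = replace(
            base,
            P_L=Gaussian(0.0, 1e-6), P_R=Gaussian(0.0, 1e-6),
            D=empirical_priors[cond],
            flat=False,
        )
        cfg_c = replace(cfg, seed=(cfg.seed + CONDITION_INDEX[cond]) % (2**31 - 1))
        per_condition[cond.value] = _fit_cells(cells[:4], cells[4], pri, cfg_c)

    rng = np.random.default_rng(cfg.seed)
    b = {c: per_condition[c].samples["B_N"].copy() for c in "LNR"}
    s = {c: per_condition[c].samples["S_N"].copy() for c in "LNR"}
    for c in "LNR":
        rng.shuffle(b[c])
    samples = {
        "B_L": b["L"], "B_N": b["N"], "B_R": b["R"],
        "S_L": s["L"], "S_N": s["N"], "S_R": s["R"],
        "D": b["N"],
        "P_L": b["L"] - b["N"],
        "P_R": b["R"] - b["N"],
    }
    means = {k: float(np.mean(v)) for k, v in samples.items()}
    sds = {k: float(np.std(v)) for k, v in samples.items()}
    return BaselineSummary(
        samples=samples, means=means, sds=sds,
        n_trials_used=n_total, per_condition=per_condition,
    )
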