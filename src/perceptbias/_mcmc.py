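"""Componentwise adaptive random-walk Metropolis core for the bias model.

The model has at most 12 free parameters, laid out in a flat vector:

    0: P_L   1: P_R   2: D
    3: log S_L   4: log S_N   5: log S_R
    6-8:  logit lambda1 (L, N, R)
    9-11: logit lambda2 (L, N, R)

Sensory noise is sampled on the log scale and lapse rates on the logit
scale; the prior terms below include the corresponding Jacobians.  The
likelihood is evaluated on trials aggregated into (condition, stimulus)
cells with binomial counts, which makes a full-session evaluation cost
~33 cells regardless of trial count.

Scale adaptation (Robbins-Monro toward a 0.44 per-component acceptance
rate) runs only during burn-in; the retained draws come from a fixed
kernel, preserving detailed balance.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NPAR = 12
_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _log_posterior(
    params,
    cell_cond,
    cell_omega,
    cell_n,
    cell_k,
    bias_mean,
    bias_sd,
    flat_biases,
    gamma_shape,
    gamma_rate,
    beta_a,
    beta_b,
    fix_lapses,
    fix_S,
    fixed_S,
):
    # empirical biases implied by the decomposition B_L=P_L+D, B_N=D, B_R=P_R+D
    B = np.empty(3)
    B[0] = params[0] + params[2]
    B[1] = params[2]
    B[2] = params[1] + params[2]

    S = np.empty(3)
    lam1 = np.zeros(3)
    lam2 = np.zeros(3)
    for c in range(3):
        if fix_S:
            S[c] = fixed_S[c]
        else:
            S[c] = math.exp(params[3 + c])
        if not fix_lapses:
            lam1[c] = 1.0 / (1.0 + math.exp(-params[6 + c]))
            lam2[c] = 1.0 / (1.0 + math.exp(-params[9 + c]))

    lp = 0.0
    # priors on the biases
    for j in range(3):
        if flat_biases:
            if params[j] < -180.0 or params[j] > 180.0:
                return -np.inf
        else:
            z = (params[j] - bias_mean[j]) / bias_sd[j]
            lp += -0.5 * z * z - math.log(bias_sd[j])
    # Gamma(shape, rate) prior on S, plus log-Jacobian of the log transform
    if not fix_S:
        for c in range(3):
            lp += gamma_shape[c] * params[3 + c] - gamma_rate[c] * S[c]
    # Beta prior on each lapse, plus logit Jacobian lam*(1-lam)
    if not fix_lapses:
        for c in range(3):
            lp += beta_a * math.log(lam1[c]) + beta_b * math.log(1.0 - lam1[c])
            lp += beta_a * math.log(lam2[c]) + beta_b * math.log(1.0 - lam2[c])

    # binomial likelihood over aggregated cells
    for i in range(cell_cond.shape[0]):
        c = cell_cond[i]
        z = (cell_omega[i] - B[c]) / S[c]
        phi = 0.5 * (1.0 + math.erf(z / _SQRT2))
        p = lam1[c] + (1.0 - lam1[c] - lam2[c]) * phi
        if p < 1e-12:
            p = 1e-12
        elif p > 1.0 - 1e-12:
            p = 1.0 - 1e-12
        lp += cell_k[i] * math.log(p) + (cell_n[i] - cell_k[i]) * math.log(1.0 - p)
    return lp


@njit(cache=True)
def run_chain(
    init,
    n_iter,
    burn_in,
    log_scales,
    free_mask,
    cell_cond,
    cell_omega,
    cell_n,
    cell_k,
    bias_mean,
    bias_sd,
    flat_biases,
    gamma_shape,
    gamma_rate,
    beta_a,
    beta_b,
    fix_lapses,
    fix_S,
    fixed_S,
    seed,
    adapt,
):
    """One MH chain; returns (draws, final state, final log-scales, acc rates)."""
    np.random.seed(seed)
    cur = init.copy()
    scales = log_scales.copy()
    cur_lp = _log_posterior(
        cur, cell_cond, cell_omega, cell_n, cell_k, bias_mean, bias_sd,
        flat_biases, gamma_shape, gamma_rate, beta_a, beta_b,
        fix_lapses, fix_S, fixed_S,
    )
    n_keep = n_iter - burn_in
    out = np.empty((n_keep, NPAR))
    n_acc = np.zeros(NPAR)
    n_try = np.zeros(NPAR)
    for it in range(n_iter):
        for j in range(NPAR):
            if not free_mask[j]:
                continue
            old = cur[j]
            cur[j] = old + math.exp(scales[j]) * np.random.normal()
            prop_lp = _log_posterior(
                cur, cell_cond, cell_omega, cell_n, cell_k, bias_mean, bias_sd,
                flat_biases, gamma_shape, gamma_rate, beta_a, beta_b,
                fix_lapses, fix_S, fixed_S,
            )
            accepted = False
            if prop_lp - cur_lp > math.log(np.random.random() + 1e-300):
                cur_lp = prop_lp
                accepted = True
            else:
                cur[j] = old
            if it >= burn_in:
                n_try[j] += 1.0
                if accepted:
                    n_acc[j] += 1.0
            elif adapt:
                step = min(0.25, 2.0 / math.sqrt(it + 2.0))
                if accepted:
                    scales[j] += step * 0.56
                else:
                    scales[j] -= step * 0.44
        if it >= burn_in:
            out[it - burn_in] = cur
    rates = np.zeros(NPAR)
    for j in range(NPAR):
        if n_try[j] > 0:
            rates[j] = n_acc[j] / n_try[j]
    return out, cur, scales, rates
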