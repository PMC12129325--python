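"""Posterior-computation tests, including an independent grid-quadrature oracle."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import ndtr

from perceptbias.inference import (
    Gaussian,
    PriorSpec,
    SamplerConfig,
    convolve_bias_priors,
    fit_baseline_empirical,
    fit_flat,
    fit_posterior,
    trials_to_cells,
)
from perceptbias.psychometric import BiasSet, ConditionLabel, TrialRecord
from perceptbias.synthetic_data import make_design, simulate_session


# ---------------------------------------------------------------------------
# independent oracle: brute-force grid quadrature over (P_L, P_R, D) with the
# noise and lapses clamped at their generating values
# ---------------------------------------------------------------------------


def grid_posterior(trials, priors, lattice, S_true=15.0):
    cond, omega, n, k, _ = trials_to_cells(trials)
    PL, PR, D = np.meshgrid(lattice, lattice, lattice, indexing="ij")
    loglik = np.zeros_like(PL)
    B_by_cond = {0: PL + D, 1: D, 2: PR + D}
    for c, om, nn, kk in zip(cond, omega, n, k):
        p = np.clip(ndtr((om - B_by_cond[int(c)]) / S_true), 1e-12, 1 - 1e-12)
        loglik += kk * np.log(p) + (nn - kk) * np.log1p(-p)
    if not priors.flat:
        for arr, g in ((PL, priors.P_L), (PR, priors.P_R), (D, priors.D)):
            loglik += -0.5 * ((arr - g.mean) / g.sd) ** 2
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    return {  # marginals on the lattice
        "P_L": w.sum(axis=(1, 2)),
        "P_R": w.sum(axis=(0, 2)),
        "D": w.sum(axis=(0, 1)),
    }


def _tv(mcmc_draws, lattice, grid_marginal):
    step = lattice[1] - lattice[0]
    edges = np.concatenate([[lattice[0] - step / 2], lattice + step / 2])
    hist, _ = np.histogram(mcmc_draws, bins=edges)
    hist = hist / hist.sum()
    return 0.5 * np.abs(hist - grid_marginal).sum()


@pytest.fixture(scope="module")
def tiny_session(truth_asym):
    # <= 60 trials on a 3-point stimulus grid
    design = make_design(grid=[-20.0, 0.0, 20.0], n_blocks=6, seed=42)  # 54 trials
    return simulate_session(design, truth_asym, S=15.0, rng=42)


class TestGridOracle:
    @pytest.mark.parametrize("flat", [False, True], ids=["informative", "flat"])
    def test_mcmc_matches_quadrature(self, tiny_session, flat):
        priors = PriorSpec(
            P_L=Gaussian(15.0, 8.0), P_R=Gaussian(-5.0, 8.0), D=Gaussian(5.0, 10.0),
            fix_S=(15.0, 15.0, 15.0), fix_lapses=True, flat=flat,
        )
        cfg = SamplerConfig(n_draws=60_000, burn_in=5_000, seed=9,
                            compute_diagnostics=False)
        post = fit_posterior(tiny_session, priors, cfg)
        lattice = np.arange(-60.0, 60.0 + 1e-9, 1.0)
        oracle = grid_posterior(tiny_session, priors, lattice)
        for name in ("P_L", "P_R", "D"):
            tv = _tv(post.samples[name], lattice, oracle[name])
            assert tv < 0.05, f"{name}: TV={tv:.3f}"

    def test_flat_prior_posterior_mean_matches_oracle_mean(self, tiny_session):
        priors = PriorSpec(fix_S=(15.0, 15.0, 15.0), fix_lapses=True, flat=True)
        cfg = SamplerConfig(n_draws=40_000, burn_in=5_000, seed=3,
                            compute_diagnostics=False)
        post = fit_posterior(tiny_session, priors, cfg)
        lattice = np.arange(-60.0, 60.0 + 1e-9, 0.5)
        oracle = grid_posterior(tiny_session, priors, lattice)
        for name in ("P_L", "P_R", "D"):
            oracle_mean = float(np.sum(lattice * oracle[name]))
            assert post.means[name] == pytest.approx(oracle_mean, abs=0.6)


class TestPosteriorStructure:
    def test_decision_bias_is_neutral_empirical_bias(self, session_factory,
                                                     priors_at_truth, quick_cfg):
        post = fit_posterior(session_factory(1, n_blocks=5), priors_at_truth, quick_cfg)
        # the identity B_N = D holds draw by draw, not just in summary
        assert np.array_equal(post.samples["B_N"], post.samples["D"])
        assert np.array_equal(post.samples["B_L"],
                              post.samples["P_L"] + post.samples["D"])

    def test_means_inside_intervals(self, session_factory, priors_at_truth, quick_cfg):
        post = fit_posterior(session_factory(2, n_blocks=5), priors_at_truth, quick_cfg)
        for name in ("P_L", "P_R", "D", "S_L"):
            lo, hi = post.ci95[name]
            assert lo <= post.means[name] <= hi
            lo68, hi68 = post.ci68[name]
            assert lo <= lo68 <= hi68 <= hi

    def test_diagnostics_reported(self, session_factory, priors_at_truth):
        cfg = SamplerConfig(n_draws=1200, burn_in=400, n_chains=2, seed=5)
        post = fit_posterior(session_factory(3, n_blocks=3), priors_at_truth, cfg)
        assert {"P_L", "D", "S_N"} <= set(post.diagnostics)
        assert all(np.isfinite(d["rhat"]) and d["ess"] > 0
                   for d in post.diagnostics.values())

    def test_empty_trials_rejected(self, priors_at_truth):
        with pytest.raises(ValueError):
            fit_posterior([], priors_at_truth)

    def test_no_neutral_trials_warns(self, session_factory, priors_at_truth, quick_cfg):
        trials = [tr for tr in session_factory(4, n_blocks=2)
                  if tr.condition is not ConditionLabel.N]
        trials = [replace_t(tr, i + 1) for i, tr in enumerate(trials)]
        with pytest.warns(RuntimeWarning, match="neutral"):
            fit_posterior(trials, priors_at_truth, quick_cfg)


def replace_t(tr: TrialRecord, t: int) -> TrialRecord:
    return TrialRecord(t=t, condition=tr.condition, omega=tr.omega, choice=tr.choice,
                       reward=tr.reward, boundary_used=tr.boundary_used)


class TestShrinkage:
    def test_degenerate_prior_dominates(self, session_factory, quick_cfg):
        m = 5.0
        priors = PriorSpec(P_L=Gaussian(m, 0.01), P_R=Gaussian(-10, 5),
                           D=Gaussian(10, 10))
        post = fit_posterior(session_factory(6, n_blocks=3), priors, quick_cfg)
        assert abs(post.means["P_L"] - m) < 0.1

    def test_wide_prior_approaches_flat(self, session_factory, quick_cfg):
        trials = session_factory(7)
        wide = PriorSpec(P_L=Gaussian(0, 1000), P_R=Gaussian(0, 1000),
                         D=Gaussian(0, 1000))
        cfg = replace(quick_cfg, n_draws=4000, burn_in=1000, seed=21)
        post_wide = fit_posterior(trials, wide, cfg)
        post_flat = fit_flat(trials, cfg)
        for name in ("P_L", "P_R", "D"):
            assert post_wide.means[name] == pytest.approx(post_flat.means[name], abs=1.0)

    def test_flat_prior_early_session_more_variable(self, session_factory,
                                                    priors_at_truth):
        trials = session_factory(8)[:100]
        cfg = SamplerConfig(n_draws=4000, burn_in=1000, seed=13,
                            compute_diagnostics=False)
        post_inf = fit_posterior(trials, priors_at_truth, cfg)
        post_flat = fit_flat(trials, cfg)
        assert post_flat.sds["P_L"] > post_inf.sds["P_L"]
        assert post_flat.sds["P_R"] > post_inf.sds["P_R"]


class TestFlatLargeN:
    def test_matches_direct_ml(self, session_factory):
        # 3 concatenated sessions; lapse-free model on both routes
        trials = []
        for s in (10, 11, 12):
            trials.extend(session_factory(s))
        trials = [replace_t(tr, i + 1) for i, tr in enumerate(trials)]
        priors = PriorSpec(fix_lapses=True, flat=True)
        cfg = SamplerConfig(n_draws=6000, burn_in=2000, seed=17,
                            compute_diagnostics=False)
        post = fit_posterior(trials, priors, cfg)

        cond, omega, n, k, _ = trials_to_cells(trials)

        def nll(x):
            pl, pr, d = x[:3]
            s = np.exp(x[3:6])
            B = {0: pl + d, 1: d, 2: pr + d}
            tot = 0.0
            for c, om, nn, kk in zip(cond, omega, n, k):
                p = np.clip(ndtr((om - B[int(c)]) / s[int(c)]), 1e-12, 1 - 1e-12)
                tot -= kk * np.log(p) + (nn - kk) * np.log1p(-p)
            return tot

        res = minimize(nll, np.array([15, -5, 5, np.log(12)] + [np.log(12)] * 2),
                       method="Nelder-Mead",
                       options={"maxiter": 6000, "xatol": 1e-6, "fatol": 1e-8})
        ml = dict(zip(["P_L", "P_R", "D"], res.x[:3]))
        for name in ("P_L", "P_R", "D"):
            assert post.means[name] == pytest.approx(ml[name], abs=0.75)


class TestConvolvedPriorsAndBaseline:
    @pytest.mark.parametrize(
        "perc, dec, expected",
        [
            (Gaussian(0, 10), Gaussian(0, 10), Gaussian(0, 14.142135623730951)),
            (Gaussian(0, 1e-12), Gaussian(0, 7.0), Gaussian(0, 7.0)),
            (Gaussian(20, 5), Gaussian(10, 5), Gaussian(30, 7.0710678118654755)),
        ],
    )
    def test_convolution_closed_form(self, perc, dec, expected):
        got = convolve_bias_priors(perc, dec)
        assert got.mean == pytest.approx(expected.mean)
        assert got.sd == pytest.approx(expected.sd)

    def test_baseline_recovery_arithmetic(self, session_factory, quick_cfg):
        truth = BiasSet(20, -10, 10)
        perc = {"L": Gaussian(20, 5), "R": Gaussian(-10, 5)}
        dec = Gaussian(10, 10)
        emp = {
            ConditionLabel.L: convolve_bias_priors(perc["L"], dec),
            ConditionLabel.N: dec,
            ConditionLabel.R: convolve_bias_priors(perc["R"], dec),
        }
        base = fit_baseline_empirical(session_factory(20, truth=truth), emp, quick_cfg)
        # recovered perceptual biases are exactly the B-differences
        assert base.means["P_L"] == pytest.approx(
            base.means["B_L"] - base.means["B_N"], abs=1e-9)
        # and variances add under independence
        expect_sd = np.hypot(base.sds["B_L"], base.sds["B_N"])
        assert base.sds["P_L"] == pytest.approx(expect_sd, rel=0.15)
        # consistency: on a full session the estimates land near the truth
        # (single-session sampling SD of a recovered P is ~2.1 deg; use ~2 SD)
        assert base.means["P_L"] == pytest.approx(20.0, abs=4.5)
        assert base.means["P_R"] == pytest.approx(-10.0, abs=4.5)

    def test_baseline_agrees_with_full_model_large_n(self, session_factory, quick_cfg):
        truth = BiasSet(20, -10, 10)
        trials = session_factory(21, truth=truth)
        perc = {"L": Gaussian(20, 5), "R": Gaussian(-10, 5)}
        dec = Gaussian(10, 10)
        emp = {
            ConditionLabel.L: convolve_bias_priors(perc["L"], dec),
            ConditionLabel.N: dec,
            ConditionLabel.R: convolve_bias_priors(perc["R"], dec),
        }
        cfg = replace(quick_cfg, n_draws=3000, burn_in=1000)
        base = fit_baseline_empirical(trials, emp, cfg)
        full = fit_posterior(
            trials,
            PriorSpec(P_L=perc["L"], P_R=perc["R"], D=dec),
            cfg,
        )
        for name in ("P_L", "P_R"):
            assert base.means[name] == pytest.approx(full.means[name], abs=2.0)


class TestConfigValidation:
    def test_sampler_config(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_draws=100, burn_in=100)
        with pytest.raises(ValueError):
            SamplerConfig(refit_cadence=0)

    def test_prior_spec(self):
        with pytest.raises(ValueError):
            PriorSpec(P_L=Gaussian(0, 0.0))
        with pytest.raises(ValueError):
            PriorSpec(S_rate=-1.0)

    def test_prior_roundtrip(self):
        p = PriorSpec(P_L=Gaussian(-10, 7), P_R=Gaussian(10, 7), D=Gaussian(0, 10),
                      fix_lapses=True)
        assert PriorSpec.from_dict(p.to_dict()).to_dict() == p.to_dict()
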