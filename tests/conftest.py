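"""Shared fixtures: canonical ground truths, priors, and session simulators."""

import numpy as np
import pytest

from perceptbias.inference import Gaussian, PriorSpec, SamplerConfig
from perceptbias.psychometric import BiasSet
from perceptbias.synthetic_data import make_design, simulate_session


@pytest.fixture(scope="session")
def truth_asym() -> BiasSet:
    """The validation ground truth: asymmetric perceptual biases and a
    substantial decision bias (P_L=+20, P_R=-10, D=+10; S=15, no lapses)."""
    return BiasSet(P_L=20.0, P_R=-10.0, D=10.0)


@pytest.fixture(scope="session")
def truth_sym() -> BiasSet:
    """The overconfidence-scenario ground truth (P_L=+20, P_R=-20, D=+10)."""
    return BiasSet(P_L=20.0, P_R=-20.0, D=10.0)


@pytest.fixture(scope="session")
def priors_at_truth(truth_asym) -> PriorSpec:
    """Informative priors centered at the generating values, SD 5 deg for the
    perceptual biases and 10 deg for the decision bias."""
    return PriorSpec(
        P_L=Gaussian(truth_asym.P_L, 5.0),
        P_R=Gaussian(truth_asym.P_R, 5.0),
        D=Gaussian(truth_asym.D, 10.0),
    )


@pytest.fixture(scope="session")
def quick_cfg() -> SamplerConfig:
    """Reduced draw count for test-suite fits where the tolerance allows it."""
    return SamplerConfig(n_draws=1500, burn_in=500, compute_diagnostics=False)


@pytest.fixture(scope="session")
def session_factory(truth_asym):
    """Callable simulating one standard 990-trial session from the observer
    model; keyword overrides pass straight through to simulate_session."""

    def make(seed: int, truth: BiasSet | None = None, n_blocks: int = 30, **kw):
        design = make_design(n_blocks=n_blocks, seed=seed)
        return simulate_session(
            design, truth if truth is not None else truth_asym,
            S=kw.pop("S", 15.0), rng=seed + 10_000, **kw,
        )

    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
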