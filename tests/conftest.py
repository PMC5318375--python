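import numpy as np
import pytest

from bcmdyn.model import (
    PlasticityRule,
    ReducedThreeStimulusSystem,
    StimulusEnsemble,
    meanfield_system,
)

ALPHA3, BETA3 = 0.92, 2.5  # the canonical three-stimulus geometry


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def standard_pair():
    """Unit stimuli at angle 1 radian, equal probabilities."""
    return StimulusEnsemble.angled_pair(1.0)


@pytest.fixture
def amplified_pair():
    """Second stimulus amplified by 1.5 (a = 2.25), equal probabilities."""
    return StimulusEnsemble.angled_pair(1.0, 1.5)


def two_stimulus_family(ensemble):
    """tau -> mean-field OdeSystem for a fixed two-stimulus ensemble."""
    return lambda tau: meanfield_system(ensemble, PlasticityRule(1.0, tau))


def reduced_family(C):
    """tau -> reduced three-stimulus OdeSystem at conservation constant C."""
    red = ReducedThreeStimulusSystem(ALPHA3, BETA3, C)
    return lambda tau: red.system(PlasticityRule(1.0, tau))


def random_noncollinear_pair(rng, rho=None):
    """Random valid two-stimulus ensemble with |x1| = 1 and a > b**2."""
    while True:
        ang = rng.uniform(0.2, np.pi - 0.2)
        amp = rng.uniform(0.5, 2.0)
        rho = rng.uniform(0.2, 0.8) if rho is None else rho
        ens = StimulusEnsemble.angled_pair(ang, amp, rho)
        a, b = ens.pair_params()
        if a - b * b > 1e-3:
            return ens
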