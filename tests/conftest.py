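import numpy as np
import pytest

from multirct import MissingnessPlan, OutcomeModel, apply_missingness, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def bivariate_trial():
    """Complete two-continuous-outcome trial, rho=.5, modest effects."""
    model = OutcomeModel(effects=[0.35, 0.35], rho=0.5)
    return simulate(model, 260, seed=42)


@pytest.fixture
def mcar_trial():
    """Two continuous outcomes, rho=.5, 30%/50% MCAR missingness."""
    model = OutcomeModel(effects=[0.35, 0.35], rho=0.5)
    data = simulate(model, 260, seed=43)
    plan = MissingnessPlan("MCAR", [0.3, 0.5])
    return apply_missingness(data, plan, seed=44)


@pytest.fixture
def mixed_trial():
    """Complete mixed pair: continuous + binary, rho=.5."""
    model = OutcomeModel(
        effects=[0.35, 0.35], rho=0.5, outcome_types=("continuous", "binary")
    )
    return simulate(model, 260, seed=45)
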