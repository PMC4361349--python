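import warnings

import pytest

import discardcast as dc

SCENARIO_SEED = 3
FIT_SEED = 1


@pytest.fixture(scope="session")
def scenario():
    """The default synthetic study: 5 reference + 3 landings-only species."""
    return dc.reference_scenario(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def full_fit(scenario):
    """Full-model fit at the standard testing MCMC size (4 x 2000+2000)."""
    model = dc.DiscardModel.from_scenario(scenario)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(draws=2000, warmup=2000, chains=4, seed=FIT_SEED)


@pytest.fixture(scope="session")
def quick_fit(scenario):
    """Small full-model fit for structural tests that don't need precision."""
    model = dc.DiscardModel.from_scenario(scenario)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(draws=400, warmup=400, chains=2, seed=FIT_SEED)
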