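import pytest

from multiturn_tof import IonSpecies, default_instrument_model, make_condition


@pytest.fixture(scope="session")
def model():
    """Default instrument model anchored on published multi-lap CO2+ TOFs."""
    return default_instrument_model()


@pytest.fixture(scope="session")
def co2():
    return IonSpecies("CO2")


@pytest.fixture(scope="session")
def gas_mixture_ions():
    """The eight-ion residual-gas mixture used throughout worked examples."""
    return [IonSpecies(f) for f in
            ["N", "O", "OH", "H2O", "[15N]N", "O2", "Ar", "CO2"]]


@pytest.fixture(scope="session")
def cond24(model, co2):
    return make_condition(co2, 24, model)
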