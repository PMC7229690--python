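import pytest

from ratdecide import ModelParams, SubtypeSpec, ThresholdTable


@pytest.fixture(scope="session")
def params_strong():
    """Strongly aligned preferences at unit habitual noise, natural conditions."""
    return ModelParams(4, 0.9, 1.0)


@pytest.fixture(scope="session")
def thresholds_strong(params_strong):
    return ThresholdTable(params_strong)


@pytest.fixture(scope="session")
def majority_minority_spec():
    """90/10 two-type population: high within-type, low between-type alignment."""
    return SubtypeSpec(gamma=0.9, rho_high=0.9, rho_low=0.25)
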