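import numpy as np
import pytest

from agevar import Scenario, ScenarioSpec, bin_edges_default

ALL_SCENARIOS = ["S1", "S2", "S3", "S4"]


@pytest.fixture(scope="session")
def default_edges():
    """10-year bins over the default 30-80 age range."""
    return bin_edges_default(30.0, 80.0, 10.0)


@pytest.fixture(params=ALL_SCENARIOS)
def default_spec(request):
    """Noise-free default ScenarioSpec, parametrised over all four scenarios."""
    return ScenarioSpec(request.param)


def spec_for(short: str, **kwargs) -> ScenarioSpec:
    return ScenarioSpec(Scenario.parse(short), **kwargs)
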