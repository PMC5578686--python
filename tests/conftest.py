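import numpy as np
import pytest

from msclgate import scenarios as sc
from msclgate.synth import SyntheticDefaults

#: Increment count used for the scenario battery: coarse enough to keep the
#: whole 11-model sweep under a couple of minutes, fine enough that the
#: displacement path is quasi-static.
SCENARIO_INCREMENTS = 16


@pytest.fixture(scope="session")
def defaults() -> SyntheticDefaults:
    return SyntheticDefaults()


@pytest.fixture(scope="session")
def scenario_results(defaults):
    """All eleven in-silico models, run once and shared across tests."""
    results = {}
    for mid in range(1, 12):
        results[mid] = sc.run_scenario(
            sc.make_scenario(mid, increments=SCENARIO_INCREMENTS), defaults=defaults
        )
    return results
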