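import numpy as np
import pytest

from hemaclone import (
    ScenarioConfig,
    get_preset,
    healthy_steady_state,
    simulate,
)


@pytest.fixture(scope="session")
def baseline():
    return get_preset("mds_baseline")


@pytest.fixture(scope="session")
def healthy():
    return get_preset("healthy_default")


@pytest.fixture(scope="session")
def baseline_ss(baseline):
    return healthy_steady_state(baseline)


@pytest.fixture(scope="session")
def disease_traj(baseline):
    """Default two-lineage scenario: healthy equilibrium + 1 MDS stem cell,
    integrated over 55 years."""
    return simulate(ScenarioConfig(params=baseline, horizon_years=55.0))


@pytest.fixture(scope="session")
def healthy_traj(healthy):
    """Healthy-only system started at its analytic equilibrium."""
    state = healthy_steady_state(healthy)
    return simulate(
        ScenarioConfig(params=healthy, initial=state, horizon_years=55.0)
    )
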