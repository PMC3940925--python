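import pandas as pd
import pytest
from hypothesis import settings

from paralomir import SimulationConfig, simulate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim():
    """One default synthetic study shared across read-only tests."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture()
def toy_counts():
    """3-entity × 2-tissue count matrix used by the manual-arithmetic oracles."""
    return pd.DataFrame(
        [[50.0, 10.0], [40.0, 5.0], [10.0, 45.0]],
        index=["e1", "e2", "e3"],
        columns=["t1", "t2"],
    )
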