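import numpy as np
import pytest
from hypothesis import settings

from burstcoast import ArenaSpec, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def single_run():
    """Moderate single-fish run at the R=250 reference condition."""
    return simulate(1, 20_000, ArenaSpec(250.0), seed=101)


@pytest.fixture(scope="session")
def single_run_large_tank():
    """Single-fish run in the largest tank (used for wall-frame statistics)."""
    return simulate(1, 20_000, ArenaSpec(353.0), seed=202)


@pytest.fixture(scope="session")
def pair_run():
    """Moderate two-fish run at the reference pair condition."""
    return simulate(2, 30_000, ArenaSpec(250.0), seed=303)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
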