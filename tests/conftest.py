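import numpy as np
import pandas as pd
import pytest

from wormlife import simulate
from wormlife.config import Config


@pytest.fixture(scope="session")
def config():
    return Config(random_seed=7, bootstrap_reps=100)


@pytest.fixture(scope="session")
def elegans_sim():
    """Continuous-mating C. elegans cohort at 25 °C, published conditions."""
    return simulate.simulate_cohort(simulate.preset("C_elegans"), n=300, seed=11)


@pytest.fixture(scope="session")
def inopinata_sim():
    return simulate.simulate_cohort(simulate.preset("C_inopinata"), n=300, seed=12)


@pytest.fixture()
def milestone_frame():
    """Tiny hand-written milestone table."""
    return pd.DataFrame(
        {
            "species": ["C_elegans"] * 6,
            "temperature": [20.0] * 6,
            "milestone": ["L4"] * 6,
            "time": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
            "status": [0, 0, 0, 1, 1, 1],
        }
    )


def make_lifespans(days, species="C_elegans", censored=None):
    n = len(days)
    return pd.DataFrame(
        {
            "species": [species] * n,
            "day_of_death": list(days),
            "censored": list(censored) if censored is not None else [False] * n,
        }
    )


@pytest.fixture()
def lifespan_factory():
    return make_lifespans


@pytest.fixture()
def rng(request):
    """Per-test deterministic generator (independent of execution order)."""
    import zlib

    seed = zlib.crc32(request.node.name.encode()) % (2**31)
    return np.random.default_rng(seed)
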