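import numpy as np
import pytest

import tvsmart as tv


@pytest.fixture(scope="session")
def table1():
    return tv.load_scenario("table1")


@pytest.fixture(scope="session")
def table1_data(table1):
    """One medium Fig.-1 trial (seeded) shared by read-only tests."""
    rng = tv.replicate_rng(42, 0)
    return tv.simulate_trial(table1.design, table1.params, 1000, rng)


@pytest.fixture(scope="session")
def small_data(table1):
    """A small trial for cheap structural tests."""
    rng = tv.replicate_rng(42, 1)
    return tv.simulate_trial(table1.design, table1.params, 250, rng)
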