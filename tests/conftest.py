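import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import bloodhts as b

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def spec():
    return b.gender_abo_hierarchy()


@pytest.fixture(scope="session")
def summing(spec):
    return b.build_summing_matrix(spec)


@pytest.fixture(scope="session")
def series144(spec):
    """Default synthetic registry: 144 months, study-condition defaults."""
    return b.generate(b.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def series60():
    """Shorter registry for fast model-fitting tests."""
    return b.generate(b.SyntheticConfig(seed=5, n_months=60))


def random_balanced_children(rng, max_fanout=4, levels=2):
    """Random strict balanced tree as a children mapping."""
    children = {}
    frontier = ["root"]
    for level in range(levels):
        nxt = []
        for parent in frontier:
            kids = [f"{parent}.{i}" for i in range(rng.integers(1, max_fanout + 1))]
            children[parent] = kids
            nxt.extend(kids)
        frontier = nxt
    return children
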