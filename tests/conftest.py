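import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cormorant_sexing as cs

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def default_config():
    return cs.default_config(seed=1234)


@pytest.fixture(scope="session")
def small_sample():
    """A quick complete-data sample at the shipped means/CVs, ~100 per sex."""
    cfg = cs.default_config(
        seed=7,
        group_sizes={"M": {"juv": 60, "ad": 40}, "F": {"juv": 60, "ad": 40}},
        missingness={m: 0.0 for m in cs.MEASUREMENTS},
    )
    return cs.generate_population(cfg)


@pytest.fixture(scope="session")
def big_sample():
    """5000 birds per sex, complete data: for moment-recovery checks."""
    cfg = cs.default_config(
        seed=99,
        group_sizes={"M": {"juv": 5000, "ad": 0}, "F": {"juv": 5000, "ad": 0}},
        missingness={m: 0.0 for m in cs.MEASUREMENTS},
    )
    return cs.generate_population(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
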