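import logging

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from myoquiesce.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

logging.getLogger("myoquiesce").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-gene default-structure cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(n_genes=400, seed=3))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted contrast anywhere (anchors disabled)."""
    cfg = SimulationConfig(
        n_genes=400, de_fraction=0.0, atp2b4_lfc=0.0, atp2a2_lfc=0.0,
        n_ptb_nq=0, n_ptb_q=0, seed=4,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
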