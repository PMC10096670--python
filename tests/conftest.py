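import numpy as np
import pytest
from hypothesis import settings

import dietgxe as dg

settings.register_profile(
    "ci", deadline=None, max_examples=50, derandomize=True
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> dg.SimulationConfig:
    return dg.SimulationConfig(
        n_samples=800, n_variants=40, n_blocks=4, block_r=0.0, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> dg.SyntheticCohort:
    return dg.simulate.simulate(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    return dg.analysis_table(small_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
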