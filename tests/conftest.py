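import numpy as np
import pytest

from asymkit import SimulationConfig, generate_cohort
from asymkit.simulate import make_fixture_suite


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-condition cohort shared across read-only tests."""
    return generate_cohort(
        SimulationConfig(seed=11, n_male=30, n_female=30)
    )


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory):
    """The canonical generated fixture file set (toy, mini cohort, broken)."""
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixture_suite(out, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
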