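import numpy as np
import pytest

from morpholong import SimulationParams, make_template, simulate_cohort


@pytest.fixture(scope="session")
def template():
    """Small symmetric quasi-landmark template (k = 130)."""
    return make_template(k_half=60, seed=3)


@pytest.fixture(scope="session")
def cohort(template):
    """Default-condition cohort at reduced size: 8 subjects x 3 stages."""
    params = SimulationParams(n_subjects=8, seed=42)
    design, configs, truth = simulate_cohort(template, params)
    return design, configs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
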