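import numpy as np
import pytest

from scanmorph import SyntheticParams, make_template, simulate_dataset


@pytest.fixture(scope="session")
def small_template():
    """50-point symmetric template with sliders and bilateral map."""
    return make_template(n_pairs=15, n_midline=8, seed=2)


@pytest.fixture(scope="session")
def small_study():
    """A reduced two-device replicate study with ground truth."""
    params = SyntheticParams(
        n_individuals=8,
        replicates=3,
        n_pairs=15,
        n_midline=8,
        seed=11,
    )
    return simulate_dataset(params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
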