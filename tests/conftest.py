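import numpy as np
import pytest

from gjflux import pipeline, simulate


@pytest.fixture(scope="session")
def default_params():
    return simulate.MonolayerParams(seed=1)


@pytest.fixture(scope="session")
def default_field(default_params):
    """One rendered default monolayer field with ground truth (seed 1)."""
    return simulate.make_monolayer(default_params)


@pytest.fixture(scope="session")
def default_result(default_field):
    imageset, _ = default_field
    return pipeline.quantify_field(imageset)


@pytest.fixture(scope="session")
def small_params():
    """A cheap field for tests that only need plumbing, not statistics."""
    return simulate.MonolayerParams(
        field_shape=(256, 256), n_cells=6, punctae_per_cell=5, seed=11
    )


@pytest.fixture(scope="session")
def small_field(small_params):
    return simulate.make_monolayer(small_params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
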