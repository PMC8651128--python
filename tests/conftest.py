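import numpy as np
import pytest

from stdgnn import io_core, phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Six phantom study pairs (2 per class) at the default desk scale."""
    return phantom.generate_cohort(2, seed=11)


@pytest.fixture(scope="session")
def desk_cfg():
    return io_core.desk_config(seed=11)


@pytest.fixture()
def labeled_points(rng):
    """12 labeled 2-D points for graph-construction tests."""
    X = rng.normal(size=(12, 2))
    labels = np.array(["V", "E", "NV"] * 4)
    return X, labels
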