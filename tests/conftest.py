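import numpy as np
import pytest

from nucarray.fixtures import mini_embryo
from nucarray.simulator import run


@pytest.fixture(scope="session")
def mini_traj():
    """One full mini-embryo run (100 -> 200 nuclei) shared across tests."""
    return run(mini_embryo(seed=0))


@pytest.fixture(scope="session")
def mini_ds(mini_traj):
    """Normalized training dataset coarse-grained from the mini run."""
    from nucarray.pipeline import training_dataset

    return training_dataset(mini_traj, t_min=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
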