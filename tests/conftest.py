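import pytest

from phenosig.datasets import combine_experiments
from phenosig.model import SignatureModel
from phenosig.simulate import default_config, null_config, simulate_dataset


@pytest.fixture(scope="session")
def default_sim():
    """Reference study conditions with planted signal (seed 1)."""
    return simulate_dataset(default_config(seed=1))


@pytest.fixture(scope="session")
def default_data(default_sim):
    experiments, _, _ = default_sim
    return combine_experiments(experiments)


@pytest.fixture(scope="session")
def default_fit(default_data):
    """Signature fit at the generator's true latent-factor count (2 PCs)."""
    return SignatureModel(default_data, n_pcs=2).fit(n_top=200)


@pytest.fixture(scope="session")
def null_sim():
    """Same conditions with no planted signal genes."""
    return simulate_dataset(null_config(seed=1))


@pytest.fixture(scope="session")
def null_data(null_sim):
    experiments, _, _ = null_sim
    return combine_experiments(experiments)
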