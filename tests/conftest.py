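import pytest

from virosnap.resistance import default_mutation_lists
from virosnap.simulate import SimConfig, generate_trial, make_fixture


@pytest.fixture(scope="session")
def reference_dataset():
    """Deterministic fixture reproducing the trial's marginal counts."""
    return make_fixture()


@pytest.fixture(scope="session")
def small_simulated_dataset():
    return generate_trial(SimConfig(n_total=80, seed=7))


@pytest.fixture(scope="session")
def mutation_lists():
    return default_mutation_lists()
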