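import numpy as np
import pytest

from amygdecode import data_model, synthetic


@pytest.fixture(scope="session")
def catalog():
    return data_model.default_catalog()


@pytest.fixture(scope="session")
def small_preset_dataset():
    """Small mixed population with the default response presets."""
    cfg = synthetic.PopulationConfig(
        n_positive=6, n_negative=6, n_nonselective=8, n_trials=10, seed=101
    )
    return synthetic.simulate_population(config=cfg), cfg


@pytest.fixture(scope="session")
def small_null_dataset():
    cfg = synthetic.null_config(n_neurons=20, n_trials=10, seed=202)
    return synthetic.simulate_population(config=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
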