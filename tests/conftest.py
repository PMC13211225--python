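import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from accelstab.fitting import fit_model
from accelstab.simulate import first_order_scenario, generate_stability_dataset

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def first_order_cfg():
    return first_order_scenario()


@pytest.fixture(scope="session")
def first_order_data(first_order_cfg):
    """One noisy dataset from the default first-order scenario."""
    return generate_stability_dataset(first_order_cfg, seed=42).select("purity_pct")


@pytest.fixture(scope="session")
def first_order_fit(first_order_cfg, first_order_data):
    """The true one-step first-order structure fitted to that dataset."""
    truth = first_order_cfg.assays["purity_pct"]
    return fit_model(first_order_data, truth.spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
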