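import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    from pedrec import SimConfig

    return SimConfig(n_founders=60, markers_per_chrom=250, seed=31)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """One shared error-free synthetic study (60 founders x 3 generations)."""
    from pedrec.simulate import generate_dataset

    return generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
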