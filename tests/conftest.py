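import pytest
from hypothesis import HealthCheck, settings

import ferrodial as fd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def design():
    return fd.default_design()


@pytest.fixture(scope="session")
def dataset():
    return fd.generate_dataset(seed=1)


@pytest.fixture(scope="session")
def results(dataset):
    return fd.compute_table(dataset.measurements)
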