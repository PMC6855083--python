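import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Ten segments per quality class, fixed master seed."""
    from ecgsqa.rules import QualityClass
    from ecgsqa.synthetic import DatasetSpec, generate_dataset

    spec = DatasetSpec(counts={c: 10 for c in QualityClass}, seed=42)
    return generate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
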