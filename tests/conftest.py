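import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20150516)


@pytest.fixture
def small_reference():
    from bsmeth.simulate import generate_reference

    return generate_reference(5000, gc_fraction=0.5, cpg_factor=1.0, seed=42)
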