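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

from rumitrack.simulate import SimConfig, simulate_scene


@pytest.fixture(scope="session")
def clean_two_cow_scene():
    """Noiseless two-cow scene with known ground truth."""
    cfg = SimConfig(n_cows=2, duration_s=40.0, bout_length_s=(50.0, 50.0), seed=11)
    bundle, truth = simulate_scene(cfg)
    return cfg, bundle, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
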