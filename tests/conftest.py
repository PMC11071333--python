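import numpy as np
import pytest

from wristhar import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_gen_config():
    """A scaled-down benchmark used by the slower integration tests."""
    return simulate.GeneratorConfig(n_sequences=8, sequence_length_s=30.0, seed=7)


@pytest.fixture(scope="session")
def small_benchmark(small_gen_config):
    return simulate.make_benchmark(small_gen_config)


@pytest.fixture
def models():
    return simulate.default_activity_models()


@pytest.fixture
def separable_toy():
    """20 linearly separable 2-D points in two classes."""
    rng = np.random.default_rng(0)
    a = rng.normal([-2.0, -2.0], 0.3, size=(10, 2))
    b = rng.normal([2.0, 2.0], 0.3, size=(10, 2))
    x = np.vstack([a, b])
    y = np.array([0] * 10 + [1] * 10)
    return x, y
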