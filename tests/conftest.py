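import numpy as np
import pytest

from pharmasieve import synthetic


@pytest.fixture(scope="session")
def reference_models():
    return synthetic.make_reference_models()


@pytest.fixture(scope="session")
def small_benchmark(reference_models):
    """A scaled-down benchmark (12/12/5-per-active) for fast integration tests."""
    spec = synthetic.BenchmarkSpec(n_actives=12, n_inactives=12, decoys_per_active=5, seed=7)
    return synthetic.generate_benchmark(reference_models["M3"], spec), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
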