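import numpy as np
import pytest

from heritnet.synthetic_data import DesignSpec, PlantedTruth, default_truth, simulate_counts


@pytest.fixture(scope="session")
def small_spec():
    return DesignSpec(n_genes=400, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return default_truth(small_spec, n_pattern=40, n_modules=2, module_size=30)


@pytest.fixture(scope="session")
def small_dataset(small_spec, small_truth):
    counts, meta = simulate_counts(small_spec, small_truth)
    return counts, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def null_truth():
    return PlantedTruth()
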