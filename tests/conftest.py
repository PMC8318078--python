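import numpy as np
import pytest

import obmark


@pytest.fixture(scope="session")
def fixture_data():
    """Default synthetic fixture: 600 cells x 2,000 genes, seed 0."""
    matrix, truth = obmark.generate_counts(obmark.default_config(seed=0))
    return matrix, truth


@pytest.fixture(scope="session")
def fitted_pipeline(fixture_data):
    """The full marker-discovery pipeline fitted once on the default fixture."""
    matrix, _ = fixture_data
    return obmark.MarkerDiscovery(random_state=0).fit_matrix(matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
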