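import numpy as np
import pytest

from stromaniche import preprocess as pp
from stromaniche import synthetic as syn


@pytest.fixture(scope="session")
def small_dataset():
    """Five-library stromal dataset, small enough for unit tests."""
    cfg = syn.default_config(n_genes=300, n_cells_per_library=400, seed=11)
    return syn.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    adata = small_dataset.adata.copy()
    pp.log_normalize(adata)
    return adata


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
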