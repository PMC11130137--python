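import numpy as np
import pytest

import nestwebs as nw


@pytest.fixture(scope="session")
def catalog():
    return nw.default_catalog()


@pytest.fixture(scope="session")
def adjacency():
    return nw.default_general_adjacency()


@pytest.fixture(scope="session")
def small_dataset():
    """A 12-nest dataset from the study-like preset (fast, deterministic)."""
    cfg = nw.preset_studylike(seed=7)
    cfg.n_nests = 12
    return nw.generate_dataset(cfg)


@pytest.fixture(scope="session")
def preset_dataset():
    """A full 51-nest dataset from the study-like preset."""
    return nw.generate_dataset(nw.preset_studylike(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
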