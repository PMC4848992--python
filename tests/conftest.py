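import numpy as np
import pytest

from anthraqsar import chemio


@pytest.fixture(scope="session")
def fxr_table():
    return chemio.load_fxr_table()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160408)


@pytest.fixture(scope="session")
def small_conformer():
    """Methane conformer, reused where any 3D molecule will do."""
    return chemio.generate_conformer("C", seed=7)
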