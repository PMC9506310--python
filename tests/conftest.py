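import numpy as np
import pytest
from hypothesis import settings

from emoconn.montage import build_montage, classify_pairs

# deterministic hypothesis runs
settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage():
    return build_montage()


@pytest.fixture(scope="session")
def pairs(montage):
    return classify_pairs(montage)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
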