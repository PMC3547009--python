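import numpy as np
import pytest

from tonemmn.montage import build_adjacency, build_paper_montage


@pytest.fixture(scope="session")
def paper_montage():
    return build_paper_montage()


@pytest.fixture(scope="session")
def paper_adjacency(paper_montage):
    return build_adjacency(paper_montage)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
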