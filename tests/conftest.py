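import numpy as np
import pytest

from assocdesign import FoldedSFS


@pytest.fixture(scope="session")
def neutral_sfs() -> FoldedSFS:
    return FoldedSFS.neutral()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20131106)
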