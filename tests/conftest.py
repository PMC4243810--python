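import numpy as np
import pytest

from lygevol.align import ScoringScheme


@pytest.fixture(scope="session")
def simple_scheme():
    return ScoringScheme.simple(match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20140188)
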