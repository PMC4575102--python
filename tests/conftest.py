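import numpy as np
import pytest

from lswspec.wavelets import build_filter


@pytest.fixture(scope="session")
def haar():
    return build_filter("haar")


@pytest.fixture(scope="session")
def la6():
    return build_filter("least-asymmetric", 6)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
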