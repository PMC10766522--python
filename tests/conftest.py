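import numpy as np
import pytest

import yycodec as yy
from yycodec.rules import REFERENCE_SCHEME
from yycodec.synthetic import SyntheticSpec, gen_file


@pytest.fixture(scope="session")
def ref_scheme():
    return REFERENCE_SCHEME


@pytest.fixture(scope="session")
def small_file():
    """3 KB balanced random file."""
    return gen_file(SyntheticSpec(size_bytes=3000, seed=101))


@pytest.fixture(scope="session")
def small_pool(small_file, ref_scheme):
    """Encoded pool of the 3 KB file under the default oligo layout."""
    return yy.encode_file(small_file, ref_scheme, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
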