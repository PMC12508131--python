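import numpy as np
import pytest

from relapsetrace.catalog import bundled_catalog
from relapsetrace.reference import ContextLocusIndex, synthesize_reference


@pytest.fixture(scope="session")
def reference():
    return synthesize_reference()


@pytest.fixture(scope="session")
def locus_index(reference):
    return ContextLocusIndex(reference)


@pytest.fixture(scope="session")
def catalog():
    return bundled_catalog()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
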