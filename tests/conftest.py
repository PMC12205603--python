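import numpy as np
import pytest

from astrotau.sites import IsoformSet


@pytest.fixture(scope="session")
def isoforms() -> IsoformSet:
    return IsoformSet.reference()


@pytest.fixture(scope="session")
def canonical(isoforms) -> str:
    return isoforms.canonical_sequence


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
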