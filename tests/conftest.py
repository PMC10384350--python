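import numpy as np
import pytest

from saponinms import reference
from saponinms.fragmenter import FragmentationConfig, theoretical_spectrum


@pytest.fixture(scope="session")
def psolusoside_c1():
    return reference.psolusoside_c1()


@pytest.fixture(scope="session")
def psolusoside_e():
    return reference.psolusoside_e()


@pytest.fixture(scope="session")
def psolusoside_a():
    return reference.psolusoside_a()


@pytest.fixture(scope="session")
def c1_nominal_mzs(psolusoside_c1):
    frags = theoretical_spectrum(psolusoside_c1, FragmentationConfig(mode="nominal"))
    out = {}
    for f in frags:  # keep the first (primary) assignment per integer m/z
        out.setdefault(round(f.mz), f)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
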