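import numpy as np
import pytest

from rpmspin.rp_model import KineticsParams
from rpmspin.synthetic_data import paper_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Published constants bundle: pathway params, isotope table, tables."""
    return paper_fixtures()


@pytest.fixture(scope="session")
def ref_kinetics():
    """Reference kinetics of the headline figures: k = 2e6, r = 1e6 s⁻¹."""
    return KineticsParams(k=2e6, r=1e6)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
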