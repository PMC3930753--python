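import numpy as np
import pytest

from varscape import SiteTimeMatrix


@pytest.fixture
def worked_matrix() -> SiteTimeMatrix:
    """Small 2x3 matrix whose components are all known by hand:
    sample convention -> Var(Y)=9, Var(Z)=18, sum spatial var=7,
    synchrony sum=4, persistence sum=11."""
    return SiteTimeMatrix("worked", [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
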