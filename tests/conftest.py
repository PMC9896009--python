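import numpy as np
import pandas as pd
import pytest

from diallelkit import DiallelDesign, simdata


@pytest.fixture
def design5():
    return DiallelDesign.from_n_parents(5)


@pytest.fixture
def design8():
    return DiallelDesign.from_n_parents(8)


@pytest.fixture
def design15():
    return DiallelDesign.from_n_parents(15)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_geno():
    return simdata.simulate_founders(8, 400, missing_rate=0.05, seed=11)


def cross_series(values, design):
    """Series of cross means indexed by canonical cross tuples."""
    return pd.Series(list(values),
                     index=pd.Index(design.crosses, tupleize_cols=False))
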