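import numpy as np
import pytest
from hypothesis import settings

from bpscreen.parameters import default_parameters
from bpscreen.risk_engine import LifeTable, load_life_table

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return load_life_table()


@pytest.fixture(scope="session")
def deathless_table():
    """A life table with no background mortality (terminal age excepted)."""
    ages = np.arange(40, 101)
    q = np.zeros(ages.size)
    q[-1] = 1.0
    return LifeTable(ages=ages, qx={"male": q.copy(), "female": q.copy()})
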