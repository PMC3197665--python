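import numpy as np
import pytest

from dbhkit.constraints import default_dbh_constraints
from dbhkit.seqstats import load_dbh_sequence


@pytest.fixture(scope="session")
def dbh_sequence() -> str:
    return load_dbh_sequence()


@pytest.fixture(scope="session")
def dbh_constraints(dbh_sequence):
    return default_dbh_constraints(dbh_sequence)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
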