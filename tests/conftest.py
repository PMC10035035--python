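import numpy as np
import pytest

from solusaxs.composition import CompositionLedger


@pytest.fixture(scope="session")
def q20():
    """20 log-spaced Q points over the beamline-like range."""
    return np.geomspace(0.004, 0.5, 20)


@pytest.fixture(scope="session")
def q200():
    return np.geomspace(0.004, 0.5, 200)


@pytest.fixture()
def dppc_ledger():
    return CompositionLedger.from_names({"DPPC": 2.5})


@pytest.fixture()
def dppc_sds_ledger():
    return CompositionLedger.from_names({"DPPC": 2.5, "SDS": 10.0})
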