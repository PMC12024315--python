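import numpy as np
import pytest

from vavr.io import load_fixture


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def table4_cell(table4, size_class, state, metric="dp_mmhg"):
    sel = table4[(table4["size_class"] == size_class)
                 & (table4["state"] == state)]
    return sel.sort_values("patient_id")[metric].to_numpy()
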