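import numpy as np
import pytest

from algaesettle import datasets, rsm


@pytest.fixture(scope="session")
def ccd_table() -> rsm.DesignTable:
    return datasets.load_ccd_table()


@pytest.fixture(scope="session")
def factors() -> tuple[rsm.Factor, ...]:
    return rsm.DEFAULT_FACTORS


@pytest.fixture(scope="session")
def cs_efficiency_fit(ccd_table):
    return rsm.fit_quadratic(ccd_table, "cs_efficiency_pct")


@pytest.fixture(scope="session")
def cs_time_fit(ccd_table):
    return rsm.fit_quadratic(ccd_table, "cs_time_h")


@pytest.fixture(scope="session")
def mc_efficiency_fit(ccd_table):
    return rsm.fit_quadratic(ccd_table, "mc_efficiency_pct")


@pytest.fixture(scope="session")
def mc_time_fit(ccd_table):
    return rsm.fit_quadratic(ccd_table, "mc_time_h")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
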