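import numpy as np
import pytest

import bcscreen as bc


@pytest.fixture(scope="session")
def params():
    return bc.load_parameters()


@pytest.fixture(scope="session")
def life_table():
    return bc.default_life_table()


@pytest.fixture(scope="session")
def incidence():
    return bc.default_incidence_curve()


@pytest.fixture(scope="session")
def strategies():
    return bc.default_strategies()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251)


def cohort_at_40(n: int, seed: int = 1) -> bc.Cohort:
    return bc.Cohort(entry_ages=np.full(n, 40, dtype=np.int16), seed=seed)


@pytest.fixture(scope="session")
def small_cohort():
    return cohort_at_40(2_000)
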