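import pytest

from cole1sim.network import build_network, load_parameters, load_study_table


@pytest.fixture(scope="session")
def low_network():
    return build_network("low")


@pytest.fixture(scope="session")
def high_network():
    return build_network("high")


@pytest.fixture(scope="session")
def low_params():
    return load_parameters("low")


@pytest.fixture(scope="session")
def high_params():
    return load_parameters("high")


@pytest.fixture(scope="session")
def study_table():
    return load_study_table()


@pytest.fixture(scope="session")
def calibrated_low():
    from cole1sim.study import calibrate
    return calibrate("low", n_starts=4, seed=1)


@pytest.fixture(scope="session")
def calibrated_high():
    from cole1sim.study import calibrate
    return calibrate("high", n_starts=4, seed=1)
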