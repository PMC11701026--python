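import pytest

from nanocal import thermo


@pytest.fixture(scope="session")
def table():
    return thermo.load_thermo_table()


@pytest.fixture(scope="session")
def composition():
    return thermo.ecoli_composition()
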