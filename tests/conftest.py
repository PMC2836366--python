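import pytest

from magshell import standard_cell, standard_stimulus


@pytest.fixture
def cell():
    return standard_cell()


@pytest.fixture
def stimulus():
    return standard_stimulus()
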