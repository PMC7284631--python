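import logging

import pytest

from lungpk import default_design, default_fixtures


@pytest.fixture(scope="session")
def fixtures():
    logging.getLogger("lungpk").setLevel(logging.ERROR)  # silence the LIN fu notice
    return default_fixtures()


@pytest.fixture(scope="session")
def phys(fixtures):
    return fixtures["salmeterol"][1]


@pytest.fixture(scope="session")
def design():
    return default_design()
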