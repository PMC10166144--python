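import pytest

import readstitch as rs


@pytest.fixture(scope="session")
def clean_world():
    return rs.generate_world(rs.preset("clean-haploid"))


@pytest.fixture(scope="session")
def repeat_world():
    return rs.generate_world(rs.preset("two-copy-repeat"))


@pytest.fixture(scope="session")
def chimera_world():
    return rs.generate_world(rs.preset("chimera"))
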