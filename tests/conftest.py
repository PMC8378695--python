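import pytest

from menzerath import default_sonority_table


@pytest.fixture(scope="session")
def table():
    return default_sonority_table()
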