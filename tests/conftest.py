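import pytest

from ondansetron_cea import builtin_scenario


@pytest.fixture(scope="session")
def us():
    return builtin_scenario("us_2006")


@pytest.fixture(scope="session")
def canada():
    return builtin_scenario("canada_2006")
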