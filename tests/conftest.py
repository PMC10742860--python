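import pytest

from shidr import PulseSchedule, get_scheme


@pytest.fixture(scope="session")
def scheme1():
    return get_scheme("scheme1")


@pytest.fixture(scope="session")
def scheme2():
    return get_scheme("scheme2")


@pytest.fixture(scope="session")
def scheme3():
    return get_scheme("scheme3")


@pytest.fixture
def base_schedule():
    """The reference control setting: phi=0.2, T=2, tau=1."""
    return PulseSchedule(phi=0.2, T=2.0, tau=1.0)
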