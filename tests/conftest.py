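import numpy as np
import pytest

from editchains import EditFamily, build_host, fixture_host


def path_host(m: int):
    """Path with m edges; edge k joins vertices k+1 and k+2."""
    return build_host([(i, i + 1) for i in range(1, m + 1)])


@pytest.fixture
def p3():
    return fixture_host("p3")


@pytest.fixture
def p3_quarter(p3):
    """The worked two-edge path instance with p_a = p_b = 0.25."""
    return p3, np.array([0.25, 0.25])


@pytest.fixture
def k3():
    return fixture_host("kn:3")


@pytest.fixture
def k4():
    return fixture_host("k4")


@pytest.fixture
def simple_p3_quarter(p3_quarter):
    host, p = p3_quarter
    return host, p, EditFamily.simple_process(host, p)
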