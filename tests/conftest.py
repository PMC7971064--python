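import pytest

from nashmri.phantom import ProbeModel, build_trajectory
from nashmri.phantom.trajectory import state_from_means


@pytest.fixture(scope="session")
def trajectory():
    return build_trajectory()


@pytest.fixture(scope="session")
def probe():
    return ProbeModel()


@pytest.fixture(scope="session")
def mean_state(trajectory):
    """Factory for the zero-dispersion 'group-mean animal'."""
    def _make(diet, week):
        return state_from_means(trajectory, diet, week)
    return _make
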