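import numpy as np
import pytest

from plumespect.spectral import TimeSeriesSet, WindowSpec
from plumespect.surrogate import SurrogateSpec, build_kernel, sample_signals


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_series(rng):
    """4 collinear sources of correlated noise, ~24 one-second windows."""
    T, S = 400, 4
    shared = rng.standard_normal((T, 1))
    values = 0.6 * shared + 0.8 * rng.standard_normal((T, S))
    positions = np.column_stack([np.zeros(S), np.arange(S) * 0.0075])
    return TimeSeriesSet(values, sample_rate=32.0, positions=positions, pitch=0.025)


@pytest.fixture
def boxcar():
    return WindowSpec(length_s=1.0, shape="boxcar", overlap=0.5)


@pytest.fixture(scope="session")
def equal_informative_sample():
    spec = SurrogateSpec(kernel="equal_informative", n_realizations=2000)
    return sample_signals(build_kernel(spec), seed=11)


@pytest.fixture(scope="session")
def high_gt_low_sample():
    spec = SurrogateSpec(kernel="high_gt_low", n_realizations=2000)
    return sample_signals(build_kernel(spec), seed=11)
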