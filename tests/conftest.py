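import numpy as np
import pytest

from mdssp import NLRDParams, QuantileSpec, fixture_failure_times


@pytest.fixture(scope="session")
def failure_times() -> np.ndarray:
    """The 30 repairable-component failure times bundled with the package."""
    return fixture_failure_times()


@pytest.fixture
def median_life_spec() -> QuantileSpec:
    """Median-anchored life test at termination ratio 0.5, quantile ratio 2."""
    return QuantileSpec(q=0.5, ratio=2.0, k=0.5)


@pytest.fixture
def params() -> NLRDParams:
    return NLRDParams(theta=1.5, lam=1.5, sigma=1.0)
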