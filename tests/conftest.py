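import numpy as np
import pytest

from fscvmodels import (
    GeometryParams,
    PlasticityParams,
    ReleaseUptakeParams,
    make_repeated_burst,
    make_single_burst,
)

#: Published wildtype sweep-1 kinetics, used as the canonical parameter set.
WT_P = (0.0105, -0.003, -0.0011)
WT_TAU = (7.5, 15.0, 900.0)


@pytest.fixture(scope="session")
def wt_kinetics() -> PlasticityParams:
    return PlasticityParams(p=WT_P, tau=WT_TAU)


@pytest.fixture(scope="session")
def flat_kinetics() -> PlasticityParams:
    """No plasticity: all factors zero, A(t) = 1."""
    return PlasticityParams(p=(0.0, 0.0, 0.0), tau=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def single_burst():
    return make_single_burst(2.0)


@pytest.fixture(scope="session")
def repeated_burst():
    return make_repeated_burst(2.0)


@pytest.fixture(scope="session")
def wt_release() -> ReleaseUptakeParams:
    return ReleaseUptakeParams(da_p=0.420, v_m=4.8)


@pytest.fixture(scope="session")
def geometry() -> GeometryParams:
    return GeometryParams()


@pytest.fixture(scope="session")
def fine_grid_12s() -> np.ndarray:
    return np.arange(0.0, 12.0001, 1e-3)
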