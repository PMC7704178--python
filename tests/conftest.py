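import numpy as np
import pytest

from dpdce import (
    AcquisitionProtocol,
    Aif,
    DpParams,
    TimeGrid,
    ToftsParams,
    population_aif,
)


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def grid(protocol):
    return protocol.dynamic_grid()


@pytest.fixture(scope="session")
def aif(grid):
    """Population AIF on the 180-point, 2 s dynamic grid."""
    return population_aif(grid)


@pytest.fixture(scope="session")
def fine_grid():
    """Refined grid (0.25 s) covering the same 6 min window."""
    return TimeGrid.uniform(180 * 8, 0.25)


@pytest.fixture(scope="session")
def fine_aif(fine_grid):
    return population_aif(fine_grid)


@pytest.fixture(scope="session")
def wildtype_dp():
    """Typical IDH-wildtype glioma DP parameters (group medians)."""
    return DpParams(f=12.48, ps=3.38, ve=9.30, vp=1.59)


@pytest.fixture(scope="session")
def mutant_dp():
    """Typical IDH-mutant glioma DP parameters (group medians)."""
    return DpParams(f=9.21, ps=0.21, ve=0.25, vp=0.21)


@pytest.fixture(scope="session")
def wildtype_tofts():
    return ToftsParams(ktrans=0.07, ve=0.1001)


@pytest.fixture(scope="session")
def mutant_tofts():
    return ToftsParams(ktrans=0.02, ve=0.0024)
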